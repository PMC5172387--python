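"""Benjamini–Hochberg false discovery rate control for heritability maps."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr"]


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """BH step-up at level q.

    Returns (flags, threshold) where ``threshold`` is the largest p-value
    declared significant (0.0 when nothing passes). Used pooled across all
    vertices and structures of one measure by default; callers may restrict
    the pool to a single structure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, threshold
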