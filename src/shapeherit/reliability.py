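"""Test–retest reliability of vertex-wise shape measures.

Scan–rescan agreement is summarized per vertex by the intraclass
correlation coefficient. The default form is the two-way random-effects,
absolute-agreement, single-measurement ICC(2,1):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

from the subjects x sessions ANOVA mean squares (MSR rows/subjects, MSC
columns/sessions, MSE residual), with k = 2 sessions. The one-way ICC(1,1)
is available via ``form='icc1_1'``. Negative estimates are retained:
clamping would bias reliability summaries upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .population import HeritabilityMap

logger = logging.getLogger(__name__)

__all__ = ["ICCMap", "TestRetestICC", "icc", "concordance", "map_correlation"]


@dataclass
class ICCMap:
    """Per-vertex test–retest ICC for one measure."""

    values: np.ndarray  # in [-1, 1], NaN where between-subject variance is 0
    n_subjects: int
    measure: str = "radial_distance"
    form: str = "icc2_1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("ICC values must lie in [-1, 1]")

    @property
    def n_vertices(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"vertex": np.arange(self.n_vertices), "icc": self.values}
                     ).to_csv(path, sep="\t", index=False)


class TestRetestICC(BaseEstimator):
    """Vectorized two-session ICC across all vertices at once.

    Parameters
    ----------
    form : 'icc2_1' (two-way random, absolute agreement, default) or
           'icc1_1' (one-way random).

    Attributes (after ``fit(scan1, scan2)``)
    ----------------------------------------
    icc_ : (V,) array; NaN marks vertices with zero between-subject variance
    n_undefined_ : int
    """

    def __init__(self, form: str = "icc2_1"):
        self.form = form

    def fit(self, scan1, scan2):
        Y1 = np.atleast_2d(np.asarray(scan1, dtype=float))
        Y2 = np.atleast_2d(np.asarray(scan2, dtype=float))
        if Y1.shape != Y2.shape:
            raise ValueError("scan matrices must have identical shape")
        n = Y1.shape[0]
        if n < 3:
            raise ValueError("ICC needs at least 3 subjects with rescans")
        k = 2.0
        grand = (Y1 + Y2).sum(axis=0) / (k * n)
        row_mean = (Y1 + Y2) / k  # (n, V) subject means
        col1 = Y1.mean(axis=0)
        col2 = Y2.mean(axis=0)
        ss_rows = k * ((row_mean - grand) ** 2).sum(axis=0)
        ss_cols = n * ((col1 - grand) ** 2 + (col2 - grand) ** 2)
        ss_total = ((Y1 - grand) ** 2 + (Y2 - grand) ** 2).sum(axis=0)
        msr = ss_rows / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.form == "icc2_1":
                mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
                msc = ss_cols / (k - 1)
                denom = msr + (k - 1) * mse + k * (msc - mse) / n
            elif self.form == "icc1_1":
                msw = (ss_total - ss_rows) / (n * (k - 1))
                denom = msr + (k - 1) * msw
                mse = msw
            else:
                raise ValueError(f"unknown ICC form {self.form!r}")
            vals = np.where(denom > 0, (msr - mse) / np.where(denom > 0, denom, 1.0), np.nan)
        self.icc_ = vals
        self.n_undefined_ = int(np.isnan(vals).sum())
        self.n_subjects_ = n
        if self.n_undefined_:
            logger.info("%d vertices have undefined ICC (no between-subject variance)",
                        self.n_undefined_)
        return self


def icc(scan1, scan2, form: str = "icc2_1", measure: str = "radial_distance") -> ICCMap:
    """Per-vertex test–retest ICC map from two scan sessions."""
    from .mesh import ShapeMeasureMatrix
    if isinstance(scan1, ShapeMeasureMatrix):
        measure = scan1.measure
        scan1 = scan1.values
    if isinstance(scan2, ShapeMeasureMatrix):
        scan2 = scan2.values
    est = TestRetestICC(form=form).fit(scan1, scan2)
    return ICCMap(est.icc_, n_subjects=est.n_subjects_, measure=measure, form=form)


def concordance(h2map: HeritabilityMap, iccmap: ICCMap) -> dict:
    """Heritability–reproducibility concordance for one structure.

    Pearson and Spearman correlations over vertices where both maps are
    defined, plus the paired table for scatter plots. Vertices with
    undefined ICC are excluded with a logged count.
    """
    if h2map.n_vertices != iccmap.n_vertices:
        raise ValueError("h2 and ICC maps cover different vertex counts")
    ok = np.isfinite(iccmap.values) & np.isfinite(h2map.h2)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("concordance: %d vertices excluded (undefined ICC)", n_excluded)
    h2 = h2map.h2[ok]
    ic = iccmap.values[ok]
    pearson_r, pearson_p = stats.pearsonr(h2, ic)
    spearman_r, spearman_p = stats.spearmanr(h2, ic)
    return {
        "pearson_r": float(pearson_r), "pearson_p": float(pearson_p),
        "spearman_r": float(spearman_r), "spearman_p": float(spearman_p),
        "n_vertices": int(ok.sum()), "n_excluded": n_excluded,
        "structure": h2map.structure, "measure": h2map.measure,
        "pairs": pd.DataFrame({"h2": h2, "icc": ic}),
    }


def map_correlation(map_a: HeritabilityMap | np.ndarray,
                    map_b: HeritabilityMap | np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p between two vertex-matched maps."""
    a = map_a.h2 if isinstance(map_a, HeritabilityMap) else np.asarray(map_a, float)
    b = map_b.h2 if isinstance(map_b, HeritabilityMap) else np.asarray(map_b, float)
    if len(a) != len(b):
        raise ValueError("maps cover different vertex counts")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant map")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
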