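"""Genotype QC and genomic relationship matrix (GRM) construction.

Dosages are expected-allele-count values in [0, 2] for n subjects by M
variants. The GRM is the standard VanRaden/GCTA form

    K = W W' / M,   w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)),

with allele frequencies p_j estimated from the analysis sample. Relatedness
pruning greedily removes subjects until no off-diagonal entry exceeds the
threshold (default 0.025, i.e. closer than roughly third-degree relatives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "GRM", "filter_variants", "compute_grm", "prune_related"]


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosages plus per-variant QC metadata."""

    dosages: np.ndarray  # (n, M), values in [0, 2], NaN = missing
    variant_ids: np.ndarray
    subject_ids: np.ndarray
    maf: np.ndarray
    rsq: np.ndarray  # imputation quality
    hwe_p: np.ndarray
    call_rate: np.ndarray
    subject_call_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        self.variant_ids = np.asarray(self.variant_ids)
        self.subject_ids = np.asarray(self.subject_ids)
        for name in ("maf", "rsq", "hwe_p", "call_rate"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} must have one entry per variant")
            setattr(self, name, arr)
        if len(self.variant_ids) != m or len(self.subject_ids) != n:
            raise ValueError("id lengths inconsistent with dosage matrix")
        if self.subject_call_rate is None:
            self.subject_call_rate = 1.0 - np.isnan(self.dosages).mean(axis=1)
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def to_tsv(self, path) -> None:
        """Dosage TSV (subjects x variants) plus a sidecar variant-metadata TSV."""
        pd.DataFrame(self.dosages, index=pd.Index(self.subject_ids, name="subject"),
                     columns=self.variant_ids).to_csv(path, sep="\t")
        meta = pd.DataFrame({
            "variant": self.variant_ids, "maf": self.maf, "rsq": self.rsq,
            "hwe_p": self.hwe_p, "call_rate": self.call_rate,
        })
        meta.to_csv(str(path) + ".variants.tsv", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        meta = pd.read_csv(str(path) + ".variants.tsv", sep="\t")
        return cls(df.to_numpy(), meta["variant"].to_numpy(), df.index.to_numpy(),
                   meta["maf"].to_numpy(), meta["rsq"].to_numpy(),
                   meta["hwe_p"].to_numpy(), meta["call_rate"].to_numpy())


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with provenance."""

    K: np.ndarray  # (n, n)
    n_variants: int
    subject_ids: np.ndarray
    pruned_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.K.shape[0]
        if self.K.shape != (n, n):
            raise ValueError("K must be square")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        diag_mean = float(np.diag(self.K).mean()) if n else 1.0
        if not (0.8 <= diag_mean <= 1.2):
            logger.warning("GRM diagonal mean %.3f outside [0.8, 1.2]", diag_mean)

    @property
    def n_subjects(self) -> int:
        return self.K.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.K, index=pd.Index(self.subject_ids, name="subject"),
                     columns=self.subject_ids).to_csv(path, sep="\t")

    # --- GCTA binary dialect ---------------------------------------------
    def to_gcta(self, prefix: str) -> None:
        """Write grm.bin / grm.N.bin (float32 lower triangle) and grm.id."""
        n = self.n_subjects
        iu = np.tril_indices(n)
        vals = self.K[iu].astype(np.float32)
        vals.tofile(f"{prefix}.grm.bin")
        np.full(vals.shape, self.n_variants, dtype=np.float32).tofile(f"{prefix}.grm.N.bin")
        with open(f"{prefix}.grm.id", "w") as fh:
            for sid in self.subject_ids:
                fh.write(f"{sid}\t{sid}\n")

    @classmethod
    def from_gcta(cls, prefix: str) -> "GRM":
        ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].to_numpy()
        n = len(ids)
        vals = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32).astype(float)
        nbin = np.fromfile(f"{prefix}.grm.N.bin", dtype=np.float32)
        K = np.zeros((n, n))
        iu = np.tril_indices(n)
        K[iu] = vals
        K = K + np.tril(K, -1).T
        return cls(K, int(round(float(nbin[0]))), ids)


def filter_variants(g: GenotypeMatrix, maf_min: float = 0.01, rsq_min: float = 0.5,
                    hwe_p_min: float = 1e-6, callrate_min: float = 0.95) -> GenotypeMatrix:
    """Drop variants failing allele-frequency, imputation-quality, HWE or call-rate QC.

    Defaults exclude MAF < 1%, imputation R^2 < 0.5, HWE P < 1e-6, and
    call rate < 95%.
    """
    for name, thr in (("maf_min", maf_min), ("rsq_min", rsq_min),
                      ("hwe_p_min", hwe_p_min), ("callrate_min", callrate_min)):
        if not (0.0 <= thr <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    keep = ((g.maf >= maf_min) & (g.rsq >= rsq_min)
            & (g.hwe_p >= hwe_p_min) & (g.call_rate >= callrate_min))
    n_kept = int(keep.sum())
    logger.info("variant QC: kept %d of %d variants (MAF>=%g, Rsq>=%g, HWE P>=%g, call rate>=%g)",
                n_kept, g.n_variants, maf_min, rsq_min, hwe_p_min, callrate_min)
    if n_kept == 0:
        raise ValueError("variant QC removed all variants")
    return GenotypeMatrix(
        g.dosages[:, keep], g.variant_ids[keep], g.subject_ids,
        g.maf[keep], g.rsq[keep], g.hwe_p[keep], g.call_rate[keep],
        subject_call_rate=g.subject_call_rate,
    )


def compute_grm(g: GenotypeMatrix) -> GRM:
    """K = W W'/M with sample-frequency standardized dosages.

    Missing dosages are mean-imputed per variant before standardization, so
    they contribute zero to relatedness.
    """
    X = g.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    p = X.mean(axis=0) / 2.0
    bad = np.flatnonzero((p <= 0) | (p >= 1))
    if bad.size:
        raise ValueError(
            f"monomorphic variants reached GRM construction (indices {bad[:5].tolist()}); "
            "apply filter_variants first"
        )
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    K = W @ W.T / g.n_variants
    K = (K + K.T) / 2.0  # symmetrize against float round-off
    logger.info("GRM: n=%d subjects, M=%d variants, sample allele frequencies used",
                g.n_subjects, g.n_variants)
    return GRM(K, g.n_variants, g.subject_ids)


def prune_related(grm: GRM, threshold: float = 0.025) -> GRM:
    """Greedy relatedness pruning: no remaining off-diagonal exceeds threshold.

    While any pair is closer than ``threshold``, the subject in the most
    offending pairs is removed (ties broken by lowest index), matching a
    keep-the-maximum-unrelated-set heuristic. Removed IDs are recorded on
    the returned GRM.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    K = grm.K.copy()
    active = np.arange(grm.n_subjects)
    removed: list = []
    while True:
        sub = K[np.ix_(active, active)]
        off = sub - np.diag(np.diag(sub))
        offending = off > threshold
        if not offending.any():
            break
        counts = offending.sum(axis=1)
        worst = int(np.argmax(counts))  # argmax takes the lowest index on ties
        removed.append(grm.subject_ids[active[worst]])
        active = np.delete(active, worst)
        if len(active) < 2:
            raise ValueError("relatedness pruning left fewer than 2 subjects")
    if removed:
        logger.info("pruned %d related subjects at threshold %g", len(removed), threshold)
    return GRM(K[np.ix_(active, active)], grm.n_variants,
               grm.subject_ids[active], pruned_ids=list(grm.pruned_ids) + removed)
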