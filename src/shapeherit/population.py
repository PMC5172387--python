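"""Population (GRM-based) narrow-sense heritability, vertex by vertex.

The model for one residualized, variance-standardized phenotype y is

    y ~ N(0, sigma_g^2 K + sigma_e^2 I),      h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)

with K the genomic relationship matrix of nominally unrelated subjects.
Estimation routes:

* ``ReMLHeritability`` — exact single-GRM restricted maximum likelihood.
  One eigendecomposition K = U diag(lam) U' per cohort rotates every
  phenotype into independent coordinates; the profile log-likelihood is
  then one-dimensional in h^2 and maximized by bounded search. Significance
  of h^2 > 0 comes from the likelihood-ratio statistic against h^2 = 0,
  referred to the boundary mixture 0.5*chi2_0 + 0.5*chi2_1.
* ``HasemanElston`` — moment fast path: regression of phenotype
  cross-products y_i y_j on relatedness K_ij over all pairs i < j.
* ``permutation_p`` — nonparametric check: the LRT recomputed under random
  subject permutations of the phenotype.

Covariates (the basic age+sex model, optionally + intracranial volume or
the structure's own gross volume) are projected out by least squares before
estimation; phenotypes are then re-standardized so h^2 estimates are
variance fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .fdr import bh_fdr
from .mesh import ShapeMeasureMatrix
from .genotypes import GRM

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateModel",
    "HeritabilityMap",
    "make_design",
    "residualize",
    "ReMLHeritability",
    "HasemanElston",
    "reml_h2",
    "he_regression",
    "permutation_p",
    "h2_map",
]

MODEL_COLUMNS = {
    "basic": ("age", "sex"),
    "icv": ("age", "sex", "icv"),
    "volume": ("age", "sex", "volume"),
}


@dataclass
class CovariateModel:
    """Named covariate design with intercept; rows aligned to phenotype subjects."""

    name: str
    design: np.ndarray  # (n, p) including intercept column
    columns: tuple = ()

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be 2-D")
        rank = np.linalg.matrix_rank(self.design)
        if rank < self.design.shape[1]:
            raise ValueError(
                f"rank-deficient design for model {self.name!r}: rank {rank} < "
                f"{self.design.shape[1]} columns {self.columns}"
            )


def make_design(covariates: pd.DataFrame, model: str = "basic") -> CovariateModel:
    """Build the named design (intercept + covariate columns) from a table.

    ``model`` is one of 'basic' (age, sex), 'icv' (+ intracranial volume) or
    'volume' (+ the structure's gross volume).
    """
    if model not in MODEL_COLUMNS:
        raise ValueError(f"unknown covariate model {model!r}; choose from {sorted(MODEL_COLUMNS)}")
    cols = MODEL_COLUMNS[model]
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing} required by model {model!r}")
    X = np.column_stack([np.ones(len(covariates))] + [covariates[c].to_numpy(float) for c in cols])
    return CovariateModel(model, X, columns=("intercept", *cols))


def residualize(y: np.ndarray, model: CovariateModel) -> np.ndarray:
    """Least-squares residuals of each phenotype column on the design."""
    Y = np.asarray(y, dtype=float)
    one_dim = Y.ndim == 1
    if one_dim:
        Y = Y[:, None]
    if len(Y) != len(model.design):
        raise ValueError("phenotype and design row counts differ")
    Q, _ = np.linalg.qr(model.design)
    R = Y - Q @ (Q.T @ Y)
    return R[:, 0] if one_dim else R


def _standardize(y: np.ndarray) -> np.ndarray:
    s = y.std(ddof=1)
    if s == 0 or not np.isfinite(s):
        raise ValueError("zero-variance phenotype")
    return (y - y.mean()) / s


# ---------------------------------------------------------------------------
# vectorized ReML core


def _check_eig(grm_or_eig):
    """Accept a GRM, a raw matrix, or a precomputed (lam, U) pair."""
    if isinstance(grm_or_eig, tuple):
        lam, U = grm_or_eig
        return np.asarray(lam, float), np.asarray(U, float)
    K = grm_or_eig.K if isinstance(grm_or_eig, GRM) else np.asarray(grm_or_eig, float)
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6 * max(lam.max(), 1.0):
        raise ValueError(
            f"GRM is not positive semi-definite (min eigenvalue {lam.min():.3g}); "
            "prune related subjects or regularize the matrix"
        )
    return np.maximum(lam, 0.0), U


def _profile_nll_grid(h2: np.ndarray, lam: np.ndarray, U2: np.ndarray) -> np.ndarray:
    """-2 * profile log-likelihood (up to constant) on a shared h2 grid.

    h2: (G,), lam: (n,), U2: (n, V) squared rotated phenotypes.
    Returns (G, V).
    """
    n = lam.shape[0]
    D = h2[:, None] * (lam - 1.0)[None, :] + 1.0  # (G, n)
    logdet = np.log(D).sum(axis=1)  # (G,)
    S = (1.0 / D) @ U2  # (G, V) = sum_i u2_iv / d_gi
    return logdet[:, None] + n * np.log(S / n)


def _profile_nll_cols(h2: np.ndarray, lam: np.ndarray, U2: np.ndarray) -> np.ndarray:
    """Per-column -2 profile log-likelihood, h2: (V,), U2: (n, V) -> (V,)."""
    n = lam.shape[0]
    D = h2[None, :] * (lam - 1.0)[:, None] + 1.0  # (n, V)
    S = (U2 / D).sum(axis=0)
    return np.log(D).sum(axis=0) + n * np.log(S / n)


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _reml_fit_many(U2: np.ndarray, lam: np.ndarray, grid_size: int = 101,
                   tol: float = 1e-6, chunk: int = 4096):
    """Vectorized bounded maximization of the profile likelihood per column.

    Coarse grid on [0, 1] followed by golden-section refinement of the
    bracketing interval, all columns simultaneously. Returns
    (h2_hat, nll_hat, nll0) with nll = -2 * profile log-likelihood.
    """
    n, V = U2.shape
    out_h2 = np.empty(V)
    out_nll = np.empty(V)
    out_nll0 = np.empty(V)
    grid = np.linspace(0.0, 1.0 - 1e-9, grid_size)
    for start in range(0, V, chunk):
        u2 = U2[:, start:start + chunk]
        G = _profile_nll_grid(grid, lam, u2)  # (grid, v)
        j = np.argmin(G, axis=0)
        a = grid[np.maximum(j - 1, 0)]
        b = grid[np.minimum(j + 1, grid_size - 1)]
        # golden-section on [a, b] per column
        x1 = b - _INVPHI * (b - a)
        x2 = a + _INVPHI * (b - a)
        f1 = _profile_nll_cols(x1, lam, u2)
        f2 = _profile_nll_cols(x2, lam, u2)
        while np.max(b - a) > tol:
            take1 = f1 < f2
            b = np.where(take1, x2, b)
            a = np.where(take1, a, x1)
            x1 = b - _INVPHI * (b - a)
            x2 = a + _INVPHI * (b - a)
            f1 = _profile_nll_cols(x1, lam, u2)
            f2 = _profile_nll_cols(x2, lam, u2)
        h2 = (a + b) / 2.0
        nll = _profile_nll_cols(h2, lam, u2)
        nll0 = _profile_nll_cols(np.zeros(u2.shape[1]), lam, u2)
        # the boundary h2=0 may beat the interior refinement
        at0 = nll0 <= nll
        h2 = np.where(at0, 0.0, h2)
        nll = np.where(at0, nll0, nll)
        sl = slice(start, start + u2.shape[1])
        out_h2[sl], out_nll[sl], out_nll0[sl] = h2, nll, nll0
    return out_h2, out_nll, out_nll0


def _reml_se_many(h2: np.ndarray, lam: np.ndarray, U2: np.ndarray,
                  step: float = 1e-3) -> np.ndarray:
    """Standard errors from the numerical curvature of the profile likelihood.

    Central second difference of the (-2 ll) profile, evaluated inside
    [0, 1]; se = sqrt(2 / curvature). Flat or negative curvature gives NaN.
    """
    lo = np.clip(h2 - step, 0.0, 1.0 - 1e-9)
    hi = np.clip(h2 + step, 0.0, 1.0 - 1e-9)
    mid = (lo + hi) / 2.0
    f_lo = _profile_nll_cols(lo, lam, U2)
    f_hi = _profile_nll_cols(hi, lam, U2)
    f_mid = _profile_nll_cols(mid, lam, U2)
    h = (hi - lo) / 2.0
    curv = (f_lo - 2.0 * f_mid + f_hi) / np.maximum(h * h, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(2.0 / curv)
    se[~np.isfinite(se)] = np.nan
    return se


def _mixture_p(lrt: np.ndarray) -> np.ndarray:
    """P-value of the boundary LRT under 0.5*chi2_0 + 0.5*chi2_1."""
    lrt = np.asarray(lrt, dtype=float)
    p = np.where(lrt <= 0, 1.0, 0.5 * stats.chi2.sf(np.maximum(lrt, 0.0), df=1))
    return np.minimum(p, 1.0)


def reml_h2_many(Y: np.ndarray, grm_or_eig, tol: float = 1e-6):
    """Exact ReML h^2 for every column of Y (already residualized).

    Returns a dict of arrays: h2, se, p, lrt. Columns are standardized
    internally. An unidentifiable GRM (all eigenvalues equal, e.g. K = I)
    yields h2 = 0, p = 1 with a warning.
    """
    lam, U = _check_eig(grm_or_eig)
    Y = np.asarray(Y, dtype=float)
    one_dim = Y.ndim == 1
    if one_dim:
        Y = Y[:, None]
    sd = Y.std(axis=0, ddof=1)
    if (sd == 0).any() or not np.isfinite(sd).all():
        raise ValueError("zero-variance phenotype column")
    Z = (Y - Y.mean(axis=0)) / sd
    if np.ptp(lam) < 1e-10:
        warnings.warn("GRM eigenvalues are all equal (identity-like relatedness); "
                      "h^2 is unidentified and reported as 0", stacklevel=2)
        V = Z.shape[1]
        zero = np.zeros(V)
        return {"h2": zero, "se": np.full(V, np.nan), "p": np.ones(V), "lrt": zero}
    U2 = (U.T @ Z) ** 2
    h2, nll, nll0 = _reml_fit_many(U2, lam, tol=tol)
    lrt = nll0 - nll  # = 2 * (ll_hat - ll_0)
    se = _reml_se_many(h2, lam, U2)
    return {"h2": h2, "se": se, "p": _mixture_p(lrt), "lrt": lrt}


# ---------------------------------------------------------------------------
# estimators


class ReMLHeritability(BaseEstimator):
    """Single-GRM restricted-maximum-likelihood heritability estimator.

    Parameters
    ----------
    tol : float
        Bracket tolerance of the bounded 1-D likelihood search on h^2.

    Attributes (after ``fit(K, y)``)
    --------------------------------
    h2_ : float      estimate in [0, 1] (boundary solutions reported as such)
    se_ : float      curvature-based standard error (NaN at flat boundaries)
    pvalue_ : float  boundary-mixture LRT p-value for h^2 > 0
    lrt_ : float     likelihood-ratio statistic vs h^2 = 0
    """

    def __init__(self, tol: float = 1e-6):
        self.tol = tol

    def fit(self, K, y):
        res = reml_h2_many(np.asarray(y, float), K, tol=self.tol)
        self.h2_ = float(res["h2"][0])
        self.se_ = float(res["se"][0])
        self.pvalue_ = float(res["p"][0])
        self.lrt_ = float(res["lrt"][0])
        return self


class HasemanElston(BaseEstimator):
    """Moment heritability: regression of y_i y_j on K_ij over pairs i < j.

    With variance-standardized phenotypes the slope estimates h^2 directly.
    ``h2_`` is the slope clamped to [0, 1]; ``h2_raw_`` keeps the unclamped
    value (useful for unbiased cross-estimator comparison), ``se_`` is the
    OLS slope standard error of the pair regression.
    """

    def fit(self, K, y):
        K = K.K if isinstance(K, GRM) else np.asarray(K, float)
        y = _standardize(np.asarray(y, float))
        iu = np.triu_indices(len(y), k=1)
        x = K[iu]
        prod = y[iu[0]] * y[iu[1]]
        xc = x - x.mean()
        sxx = float(xc @ xc)
        if sxx == 0:
            raise ValueError("relatedness has no variation across pairs")
        slope = float(xc @ prod) / sxx
        resid = prod - prod.mean() - slope * xc
        dof = len(prod) - 2
        self.se_ = float(np.sqrt(resid @ resid / dof / sxx))
        self.h2_raw_ = slope
        self.h2_ = float(np.clip(slope, 0.0, 1.0))
        return self


def reml_h2(y_col, k, tol: float = 1e-6) -> tuple[float, float, float]:
    """(h2, se, p) for a single phenotype vector. Thin wrapper over the estimator."""
    est = ReMLHeritability(tol=tol).fit(k, y_col)
    return est.h2_, est.se_, est.pvalue_


def he_regression(y_col, k) -> tuple[float, float]:
    """(h2, se) from Haseman–Elston pair regression."""
    est = HasemanElston().fit(k, y_col)
    return est.h2_, est.se_


def permutation_p(y_col, k, n_perm: int = 199, seed: int = 0) -> float:
    """Permutation p-value of the ReML LRT (add-one rule, never exactly 0)."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    lam, U = _check_eig(k)
    y = _standardize(np.asarray(y_col, float))
    obs = reml_h2_many(y, (lam, U))["lrt"][0]
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    null = reml_h2_many(perms, (lam, U))["lrt"]
    return float((1 + np.sum(null >= obs)) / (1 + n_perm))


# ---------------------------------------------------------------------------
# vertex-wise maps


@dataclass
class HeritabilityMap:
    """Per-vertex (or per-component) heritability with significance flags."""

    h2: np.ndarray
    se: np.ndarray
    p: np.ndarray
    fdr_sig: np.ndarray
    model: str = "basic"
    measure: str = "radial_distance"
    structure: str = "structure"
    q: float = 0.05

    def __post_init__(self) -> None:
        for name in ("h2", "se", "p"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.fdr_sig = np.asarray(self.fdr_sig, dtype=bool)
        if not (len(self.h2) == len(self.se) == len(self.p) == len(self.fdr_sig)):
            raise ValueError("map fields must have equal length")
        if ((self.p <= 0) | (self.p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if ((self.h2 < 0) | (self.h2 > 1)).any():
            raise ValueError("h2 must lie in [0, 1]")

    @property
    def n_vertices(self) -> int:
        return len(self.h2)

    @property
    def max_h2(self) -> float:
        return float(self.h2.max())

    @property
    def argmax_vertex(self) -> int:
        return int(self.h2.argmax())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"vertex": np.arange(self.n_vertices), "h2": self.h2,
                             "se": self.se, "p": self.p, "fdr_sig": self.fdr_sig})

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model={self.model} measure={self.measure} "
                     f"structure={self.structure} q={self.q}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def h2_map(y: ShapeMeasureMatrix | np.ndarray, k, model: CovariateModel,
           q: float = 0.05, apply_fdr: bool = True) -> HeritabilityMap:
    """ReML heritability at every vertex under one covariate model.

    The GRM eigendecomposition is computed once and reused for all vertices.
    Subjects of the measures and the GRM must match (by position or by ID
    when both carry IDs).
    """
    if isinstance(y, ShapeMeasureMatrix):
        Y = y.values
        measure = y.measure
        structure = y.structure
        if isinstance(k, GRM) and y.subject_ids is not None:
            if len(k.subject_ids) != len(y.subject_ids) or not np.array_equal(
                    np.asarray(k.subject_ids), np.asarray(y.subject_ids)):
                a = set(map(str, y.subject_ids))
                b = set(map(str, k.subject_ids))
                raise ValueError(
                    "subjects of measures and GRM differ; only in measures: "
                    f"{sorted(a - b)[:5]}, only in GRM: {sorted(b - a)[:5]}"
                )
    else:
        Y = np.asarray(y, float)
        measure, structure = "score", "structure"
    R = residualize(Y, model)
    res = reml_h2_many(R, k)
    if apply_fdr:
        flags, _ = bh_fdr(res["p"], q=q)
    else:
        flags = np.zeros(len(res["p"]), dtype=bool)
    hm = HeritabilityMap(res["h2"], res["se"], res["p"], flags,
                         model=model.name, measure=measure, structure=structure, q=q)
    logger.info("h2 map (%s/%s/%s): max h2 = %.3f at vertex %d",
                structure, measure, model.name, hm.max_h2, hm.argmax_vertex)
    return hm
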