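"""Twin ACE variance-components heritability (the replication arm).

For a standardized phenotype measured on twin pairs, the classical ACE
decomposition splits variance into additive genetic (a^2), common
environment (c^2) and unique environment (e^2 = 1 - a^2 - c^2). Pair
covariance is a^2 + c^2 for monozygotic pairs and a^2/2 + c^2 for dizygotic
and opposite-sex pairs (additive model, OS pooled with DZ with sex as a
covariate). Parameters are obtained by maximizing the sum of bivariate
normal log-densities over pairs; the no-genetics hypothesis a^2 = 0 is
tested by a likelihood ratio referred to the boundary mixture
0.5*chi2_0 + 0.5*chi2_1, as in pedigree variance-components software.

Falconer's formulas, h^2 = 2 (r_MZ - r_DZ) and c^2 = 2 r_DZ - r_MZ from the
double-entered pair correlations, serve as closed-form initializer and
sanity check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize
from sklearn.base import BaseEstimator

from .fdr import bh_fdr
from .mesh import ShapeMeasureMatrix
from .population import CovariateModel, HeritabilityMap, residualize

logger = logging.getLogger(__name__)

__all__ = ["TwinCohort", "ACEEstimate", "falconer", "ACEModel", "ace_ml", "twin_h2_map"]

_ZYGOSITIES = ("MZ", "DZ", "OS")


@dataclass
class TwinCohort:
    """Paired phenotypes with zygosity labels and per-member covariates.

    ``y1``/``y2`` hold one phenotype per pair member; for vertex-wise maps
    they are (n_pairs, n_vertices) matrices. ``covariates1``/``covariates2``
    are optional aligned design tables (age, sex, ...).
    """

    y1: np.ndarray
    y2: np.ndarray
    zygosity: np.ndarray  # 'MZ' | 'DZ' | 'OS' per pair
    covariates1: pd.DataFrame | None = None
    covariates2: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y1 = np.atleast_1d(np.asarray(self.y1, dtype=float))
        self.y2 = np.atleast_1d(np.asarray(self.y2, dtype=float))
        self.zygosity = np.asarray(self.zygosity)
        if self.y1.shape != self.y2.shape:
            raise ValueError("both members must be present for every pair")
        if len(self.zygosity) != len(self.y1):
            raise ValueError("one zygosity label per pair required")
        bad = set(np.unique(self.zygosity)) - set(_ZYGOSITIES)
        if bad:
            raise ValueError(f"unknown zygosity labels {sorted(bad)}")

    @property
    def n_pairs(self) -> int:
        return len(self.y1)

    @property
    def is_mz(self) -> np.ndarray:
        return self.zygosity == "MZ"

    def column(self, j: int) -> "TwinCohort":
        """Single-vertex view of a vertex-wise cohort."""
        return TwinCohort(self.y1[:, j], self.y2[:, j], self.zygosity,
                          self.covariates1, self.covariates2)

    def to_csv(self, path) -> None:
        rows = []
        for i in range(self.n_pairs):
            for member, y in ((1, self.y1[i]), (2, self.y2[i])):
                cov = self.covariates1 if member == 1 else self.covariates2
                row = {"pair_id": i, "member": member, "zygosity": self.zygosity[i]}
                if np.ndim(y) == 0:
                    row["y"] = float(y)
                else:
                    row.update({f"v{j}": float(val) for j, val in enumerate(np.atleast_1d(y))})
                if cov is not None:
                    row.update(cov.iloc[i].to_dict())
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ACEEstimate:
    """Fitted ACE variance fractions on the standardized scale."""

    a2: float
    c2: float
    e2: float
    loglik_full: float
    loglik_null: float
    lrt: float
    p: float

    def __post_init__(self) -> None:
        if min(self.a2, self.c2, self.e2) < -1e-8:
            raise ValueError("variance fractions must be nonnegative")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1 on the standardized scale")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


def _residualize_pairs(cohort: TwinCohort) -> tuple[np.ndarray, np.ndarray]:
    """Project member covariates out of both members, then standardize jointly."""
    y1, y2 = cohort.y1.astype(float), cohort.y2.astype(float)
    if cohort.covariates1 is not None and cohort.covariates2 is not None:
        cov = pd.concat([cohort.covariates1, cohort.covariates2], ignore_index=True)
        X = np.column_stack([np.ones(len(cov))] +
                            [cov[c].to_numpy(float) for c in cov.columns])
        model = CovariateModel("twin-adjust", X, columns=("intercept", *cov.columns))
        stacked = residualize(np.concatenate([y1, y2]), model)
        y1, y2 = stacked[: len(y1)], stacked[len(y1):]
    both = np.concatenate([y1, y2])
    mu, sd = both.mean(), both.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance twin phenotype")
    return (y1 - mu) / sd, (y2 - mu) / sd


def _double_entry_corr(y1: np.ndarray, y2: np.ndarray) -> float:
    """Intraclass pair correlation via double entry (symmetric in members)."""
    a = np.concatenate([y1, y2])
    b = np.concatenate([y2, y1])
    return float(np.corrcoef(a, b)[0, 1])


def falconer(cohort: TwinCohort) -> tuple[float, float]:
    """Closed-form (h^2, c^2) from MZ and pooled DZ/OS correlations, unclamped."""
    mz = cohort.is_mz
    dz = ~mz
    if mz.sum() < 2 or dz.sum() < 2:
        raise ValueError("need at least 2 MZ and 2 DZ/OS pairs")
    y1, y2 = _residualize_pairs(cohort)
    r_mz = _double_entry_corr(y1[mz], y2[mz])
    r_dz = _double_entry_corr(y1[dz], y2[dz])
    return 2.0 * (r_mz - r_dz), 2.0 * r_dz - r_mz


def _pair_nll(a2: float, c2: float, y1, y2, coef) -> float:
    """Negative log-likelihood of standardized pairs, correlation a2*coef + c2."""
    r = np.clip(a2 * coef + c2, -0.999999, 0.999999)
    q = 1.0 - r * r
    ll = (-np.log(2 * np.pi) - 0.5 * np.log(q)
          - (y1 ** 2 + y2 ** 2 - 2.0 * r * y1 * y2) / (2.0 * q))
    return -float(ll.sum())


class ACEModel(BaseEstimator):
    """Maximum-likelihood ACE twin model on the standardized scale.

    Parameters
    ----------
    n_restarts : int
        Random restarts added to the Falconer-initialized fit.
    seed : int
        Seed for the restart draws (results are deterministic).

    Attributes (after ``fit(cohort)``)
    ----------------------------------
    a2_, c2_, e2_ : float   variance fractions, nonnegative, summing to 1
    lrt_ : float            likelihood-ratio statistic vs a^2 = 0
    pvalue_ : float         boundary-mixture p-value
    estimate_ : ACEEstimate
    """

    def __init__(self, n_restarts: int = 3, seed: int = 0):
        self.n_restarts = n_restarts
        self.seed = seed

    def fit(self, cohort: TwinCohort, y=None):
        y1, y2 = _residualize_pairs(cohort)
        coef = np.where(cohort.is_mz, 1.0, 0.5)

        def nll(theta):
            return _pair_nll(theta[0], theta[1], y1, y2, coef)

        eps = 1e-9
        bounds = [(0.0, 1.0 - eps), (0.0, 1.0 - eps)]
        constraint = {"type": "ineq", "fun": lambda t: 1.0 - eps - t[0] - t[1]}
        starts = []
        try:
            h2_f, c2_f = falconer(cohort)
            a0 = float(np.clip(h2_f, 0.0, 0.95))
            c0 = float(np.clip(c2_f, 0.0, 0.95 - a0))
            starts.append((a0, c0))
        except ValueError:
            pass
        rng = np.random.default_rng(self.seed)
        for _ in range(self.n_restarts):
            a0, c0 = rng.uniform(0, 1, 2)
            tot = a0 + c0
            if tot > 0.95:
                a0, c0 = 0.95 * a0 / tot, 0.95 * c0 / tot
            starts.append((a0, c0))
        best = None
        for x0 in starts:
            res = optimize.minimize(nll, x0, method="SLSQP", bounds=bounds,
                                    constraints=[constraint],
                                    options={"maxiter": 200, "ftol": 1e-10})
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise RuntimeError(
                f"ACE optimizer failed to converge from {len(starts)} starts "
                f"(n_pairs={cohort.n_pairs})"
            )
        a2, c2 = float(best.x[0]), float(best.x[1])
        ll_full = -float(best.fun)
        # null model: a2 = 0, optimize c2 alone
        res0 = optimize.minimize_scalar(lambda c: _pair_nll(0.0, c, y1, y2, coef),
                                        bounds=(0.0, 1.0 - eps), method="bounded",
                                        options={"xatol": 1e-8})
        ll_null = -float(res0.fun)
        lrt = max(0.0, 2.0 * (ll_full - ll_null))
        p = 1.0 if lrt <= 0 else float(min(1.0, 0.5 * stats.chi2.sf(lrt, df=1)))
        a2 = max(a2, 0.0)
        c2 = max(c2, 0.0)
        e2 = max(1.0 - a2 - c2, 0.0)
        tot = a2 + c2 + e2
        self.a2_, self.c2_, self.e2_ = a2 / tot, c2 / tot, e2 / tot
        self.lrt_ = lrt
        self.pvalue_ = p
        self.loglik_full_ = ll_full
        self.loglik_null_ = ll_null
        self.estimate_ = ACEEstimate(self.a2_, self.c2_, self.e2_,
                                     ll_full, ll_null, lrt, p)
        return self


def ace_ml(cohort: TwinCohort, n_restarts: int = 3, seed: int = 0) -> ACEEstimate:
    """Fit the ACE model; thin wrapper over :class:`ACEModel`."""
    return ACEModel(n_restarts=n_restarts, seed=seed).fit(cohort).estimate_


def twin_h2_map(y: ShapeMeasureMatrix | TwinCohort, cohort: TwinCohort | None = None,
                q: float = 0.05, apply_fdr: bool = True,
                measure: str = "radial_distance",
                structure: str = "structure") -> HeritabilityMap:
    """Vertex-wise twin heritability map (a^2 per vertex with boundary-LRT p).

    Accepts either a vertex-wise :class:`TwinCohort` (matrices in y1/y2), or
    a :class:`ShapeMeasureMatrix` plus a template cohort carrying the pair
    structure (rows 2i, 2i+1 of the matrix are members of pair i).
    """
    if isinstance(y, TwinCohort):
        vcohort = y
    else:
        if cohort is None:
            raise ValueError("supply a TwinCohort with the pair structure")
        vals = y.values
        if len(vals) != 2 * cohort.n_pairs:
            raise ValueError("measure matrix rows must be 2 * n_pairs (interleaved members)")
        vcohort = TwinCohort(vals[0::2], vals[1::2], cohort.zygosity,
                             cohort.covariates1, cohort.covariates2)
        measure, structure = y.measure, y.structure
    V = vcohort.y1.shape[1]
    h2 = np.empty(V)
    se = np.full(V, np.nan)
    p = np.empty(V)
    for j in range(V):
        est = ace_ml(vcohort.column(j))
        h2[j] = est.a2
        p[j] = est.p
    flags, _ = bh_fdr(p, q=q) if apply_fdr else (np.zeros(V, bool), 0.0)
    hm = HeritabilityMap(h2, se, p, flags, model="twin-ace",
                         measure=measure, structure=structure, q=q)
    logger.info("twin h2 map (%s/%s): max a2 = %.3f at vertex %d",
                structure, measure, hm.max_h2, hm.argmax_vertex)
    return hm
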