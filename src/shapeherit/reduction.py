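"""PCA reduction of vertex-wise measures and heritability of components.

A full principal component analysis (covariance matrix of the centered
measures; components = min(n_subjects - 1, n_vertices)) turns one
structure's vertex-wise measure into a small set of orthogonal shape
components, ordered by explained variance. Each component score vector is
then treated as a phenotype and its heritability estimated with the same
GRM/ReML machinery as the vertex-wise maps, allowing the eigenvalue
ordering to be compared with the heritability ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .genotypes import GRM
from .mesh import ShapeMeasureMatrix
from .population import CovariateModel, HeritabilityMap, h2_map

logger = logging.getLogger(__name__)

__all__ = ["PCAResult", "ShapePCA", "pca_components", "component_h2", "eigen_vs_h2_rank"]


@dataclass
class PCAResult:
    """Full PCA of one measure matrix, eigenvalues descending."""

    loadings: np.ndarray  # (n_vertices, n_components), orthonormal columns
    scores: np.ndarray  # (n_subjects, n_components)
    eigenvalues: np.ndarray  # descending, = explained variance per component
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-8 * max(self.eigenvalues[0], 1.0)):
            raise ValueError("eigenvalues must be nonincreasing")
        G = self.loadings.T @ self.loadings
        if not np.allclose(G, np.eye(G.shape[0]), atol=1e-8):
            raise ValueError("loadings must be orthonormal")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_tsv(self, prefix) -> None:
        pd.DataFrame(self.loadings).to_csv(f"{prefix}.loadings.tsv", sep="\t", index=False)
        pd.DataFrame(self.scores).to_csv(f"{prefix}.scores.tsv", sep="\t", index=False)
        pd.DataFrame({"eigenvalue": self.eigenvalues,
                      "evr": self.explained_variance_ratio}
                     ).to_csv(f"{prefix}.eigenvalues.tsv", sep="\t", index=False)


class ShapePCA(PCA):
    """Full-spectrum PCA with a deterministic sign convention.

    Components = min(n_subjects - 1, n_vertices); each loading vector is
    flipped so its largest-magnitude entry is positive, making runs and
    machines comparable.
    """

    def __init__(self):
        super().__init__(n_components=None, svd_solver="full")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 subjects")
        if np.allclose(X.var(axis=0), 0.0):
            raise ValueError("constant measure matrix has no principal components")
        self.n_components = min(X.shape[0] - 1, X.shape[1])
        super().fit(X)
        flip = np.sign(self.components_[np.arange(len(self.components_)),
                                        np.abs(self.components_).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.components_ *= flip[:, None]
        return self

    def result(self, X) -> PCAResult:
        X = np.asarray(X, dtype=float)
        scores = self.transform(X)
        return PCAResult(self.components_.T, scores,
                         self.explained_variance_.copy(),
                         self.explained_variance_ratio_.copy())


def pca_components(y: ShapeMeasureMatrix | np.ndarray) -> PCAResult:
    """Full PCA of the centered measure matrix (covariance convention)."""
    X = y.values if isinstance(y, ShapeMeasureMatrix) else np.asarray(y, float)
    est = ShapePCA().fit(X)
    res = est.result(X)
    total_var = X.var(axis=0, ddof=1).sum()
    if not np.isclose(res.eigenvalues.sum(), total_var, rtol=1e-6):
        raise AssertionError("eigenvalue sum does not conserve total variance")
    return res


def component_h2(pca: PCAResult, k: GRM | np.ndarray, model: CovariateModel,
                 n_components: int | None = None, q: float = 0.05) -> HeritabilityMap:
    """ReML heritability of each component score, as a map over components."""
    scores = pca.scores[:, :n_components] if n_components else pca.scores
    hm = h2_map(scores, k, model, q=q)
    hm.measure = "pca_component"
    return hm


def eigen_vs_h2_rank(pca: PCAResult, h2: HeritabilityMap) -> tuple[float, float]:
    """Spearman rho between eigenvalue order and heritability order.

    Tie-corrected ranks; returns (rho, p). Near-zero rho means the
    high-variance components are not the heritable ones.
    """
    m = h2.n_vertices
    if m < 3:
        raise ValueError("need at least 3 components for a rank correlation")
    if m > pca.n_components:
        raise ValueError("more heritability entries than components")
    rho, p = stats.spearmanr(pca.eigenvalues[:m], h2.h2)
    return float(rho), float(p)
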