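"""Synthetic cohorts with known ground truth for the whole pipeline.

The generators emulate the statistical structure the analysis assumes,
without any real data:

* an unrelated population cohort (default n = 3,686 subjects, the size of
  a typical population-based imaging-genetics sample) with genotype
  dosages, QC metadata, age/sex covariates and vertex-wise shape phenotypes whose per-vertex heritability
  follows a smooth spatial field with high-h^2 clusters;
* a twin cohort (default 148 MZ + 120 DZ + 82 opposite-sex pairs) whose
  pair correlations follow the additive ACE expectations a^2 + c^2 (MZ) and
  a^2/2 + c^2 (DZ/OS);
* corresponded surface meshes carrying the phenotypes as radial
  displacements of an elongated template, plus rescan sets with a spatially
  varying measurement-noise floor (implied true ICC recorded).

Genetic architecture is infinitesimal: every variant is causal with
Gaussian weights, so the per-vertex genetic value is a weighted sum of
standardized dosages with weight variance h^2_v / M. Phenotypes are built
on a unit-variance scale, so h^2 is directly the genetic variance share.
All generators are fully determined by the config seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .genotypes import GenotypeMatrix
from .mesh import (MedialCurve, ShapeMeasureMatrix, SurfaceMesh,
                   fit_medial_curve, nearest_curve_points)
from .twin import TwinCohort

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_template",
    "h2_field",
    "noise_field",
    "generate_genotypes",
    "generate_covariates",
    "simulate_vertex_phenotypes",
    "generate_twin_cohort",
    "generate_shape_cohort",
    "generate_rescan",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with cohort-realistic defaults.

    ``h2_field_spec`` is a list of (center vertex, spatial scale, peak h^2)
    Gaussian bumps; ``None`` selects two bumps peaking at 0.533 and 0.35
    (the upper end of plausible vertex-wise shape heritability).
    ``noise_field_spec`` maps to a per-vertex measurement s.d. profile:
    a baseline plus optional (center, scale, s.d.) patches; ``None`` gives
    baseline 0.5 with one poorly-reproducible patch of s.d. 2.
    """

    n_subjects: int = 3686
    n_variants: int = 10_000
    n_vertices: int = 1937
    h2_field_spec: tuple | None = None
    a2: float = 0.6  # twin additive fraction
    c2: float = 0.2  # twin shared-environment fraction
    covariate_effects: dict = field(default_factory=lambda: {"age": 0.1, "sex": 0.1})
    noise_field_spec: dict | None = None
    mz_pairs: int = 148
    dz_pairs: int = 120
    os_pairs: int = 82
    frac_low_quality: float = 0.05  # variants with imputation R^2 < 0.5
    frac_rare: float = 0.02  # variants with MAF < 0.01
    frac_low_callrate: float = 0.02
    displacement_mm: float = 0.5  # mm of radial displacement per phenotype unit
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_variants", "n_vertices",
                     "mz_pairs", "dz_pairs", "os_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not (0.0 <= self.c2 < 1.0) or not (0.0 <= self.a2 < 1.0):
            raise ValueError("a2 and c2 must lie in [0, 1)")
        if self.a2 + self.c2 >= 1.0:
            raise ValueError("a2 + c2 must be < 1 (unique environment must remain)")
        for bump in self.h2_field_spec or ():
            _, _, peak = bump
            if not (0.0 <= peak < 1.0):
                raise ValueError("peak h2 must lie in [0, 1)")
            if peak + self.c2 >= 1.0:
                raise ValueError("peak h2 + c2 must be < 1 at every vertex")
        if self.noise_field_spec is not None:
            if self.noise_field_spec.get("baseline", 0.0) < 0:
                raise ValueError("noise s.d. must be nonnegative")
            for _, _, sd in self.noise_field_spec.get("patches", ()):
                if sd < 0:
                    raise ValueError("noise s.d. must be nonnegative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("h2_field_spec") is not None:
            raw["h2_field_spec"] = tuple(tuple(b) for b in raw["h2_field_spec"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """True generative quantities stored beside every synthetic cohort."""

    h2_true: np.ndarray | None = None
    icc_true: np.ndarray | None = None
    slopes: dict | None = None
    genetic_values: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    phenotypes: np.ndarray | None = None
    a2: float | np.ndarray | None = None
    c2: float | np.ndarray | None = None
    e2: float | np.ndarray | None = None

    def to_tsv_bundle(self, prefix) -> None:
        for name in ("h2_true", "icc_true"):
            arr = getattr(self, name)
            if arr is not None:
                pd.DataFrame({name: np.asarray(arr)}).to_csv(
                    f"{prefix}.{name}.tsv", sep="\t", index=False)
        if self.slopes:
            pd.Series(self.slopes).to_csv(f"{prefix}.slopes.tsv", sep="\t", header=False)
        if self.covariates is not None:
            self.covariates.to_csv(f"{prefix}.covariates.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# spatial fields


def _default_h2_spec(n_vertices: int) -> tuple:
    scale = max(n_vertices / 12.0, 1.0)
    return ((int(0.25 * n_vertices), scale, 0.533),
            (int(0.70 * n_vertices), scale, 0.35))


def h2_field(config: SimulationConfig, positions: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the per-vertex true-h^2 field (sum of Gaussian bumps).

    ``positions`` may be template vertex coordinates (V, 3); by default the
    field lives in vertex-index space.
    """
    spec = config.h2_field_spec
    if spec is None:
        spec = _default_h2_spec(config.n_vertices)
    if positions is None:
        pos = np.arange(config.n_vertices, dtype=float)[:, None]
    else:
        pos = np.asarray(positions, dtype=float)
        if pos.ndim == 1:
            pos = pos[:, None]
    out = np.zeros(len(pos))
    for center, scale, peak in spec:
        c = pos[int(center)]
        d2 = ((pos - c) ** 2).sum(axis=1)
        out += peak * np.exp(-d2 / (2.0 * float(scale) ** 2))
    cap = min(0.95, 1.0 - config.c2 - 1e-6)
    return np.clip(out, 0.0, cap)


def noise_field(config: SimulationConfig, positions: np.ndarray | None = None) -> np.ndarray:
    """Per-vertex measurement s.d. (phenotype units): baseline + noisy patches."""
    spec = config.noise_field_spec
    if spec is None:
        spec = {"baseline": 0.5,
                "patches": ((int(0.9 * config.n_vertices), max(config.n_vertices / 20.0, 1.0), 2.0),)}
    if positions is None:
        pos = np.arange(config.n_vertices, dtype=float)[:, None]
    else:
        pos = np.asarray(positions, dtype=float)
        if pos.ndim == 1:
            pos = pos[:, None]
    out = np.full(len(pos), float(spec.get("baseline", 0.0)))
    for center, scale, sd in spec.get("patches", ()):
        c = pos[int(center)]
        d2 = ((pos - c) ** 2).sum(axis=1)
        out = np.maximum(out, sd * np.exp(-d2 / (2.0 * float(scale) ** 2)))
    return out


# ---------------------------------------------------------------------------
# genotypes


def _hwe_p(dosages: np.ndarray) -> float:
    """HWE chi-squared p from hard-called genotype counts of one variant."""
    calls = np.round(dosages[np.isfinite(dosages)]).astype(int)
    n0, n1, n2 = np.bincount(np.clip(calls, 0, 2), minlength=3)[:3]
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    p = (2 * n2 + n1) / (2 * n)
    if p <= 0 or p >= 1:
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    obs = np.array([n0, n1, n2])
    chi2 = float(((obs - exp) ** 2 / np.maximum(exp, 1e-12)).sum())
    return float(stats.chi2.sf(chi2, df=1))


def generate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Dosage matrix with QC metadata (MAF, imputation R^2, HWE P, call rate).

    Allele frequencies are uniform on [0.05, 0.5] apart from a small
    fraction of rare (MAF < 0.01) variants, and a fraction of variants
    carries imputation R^2 < 0.5 with correspondingly noisy dosages — both
    so downstream QC filters have work to do.  Variants are unlinked.
    """
    n, m = config.n_subjects, config.n_variants
    if n < 1 or m < 2:
        raise ValueError("need at least 1 subject and 2 variants")
    rng = config.rng(stream=1)
    freq = rng.uniform(0.05, 0.5, size=m)
    n_rare = int(round(config.frac_rare * m))
    if n_rare:
        rare_idx = rng.choice(m, size=n_rare, replace=False)
        freq[rare_idx] = rng.uniform(0.001, 0.009, size=n_rare)
    X = rng.binomial(2, freq, size=(n, m)).astype(float)

    rsq = rng.uniform(0.7, 1.0, size=m)
    n_lowq = int(round(config.frac_low_quality * m))
    if n_lowq:
        lowq_idx = rng.choice(m, size=n_lowq, replace=False)
        rsq[lowq_idx] = rng.uniform(0.1, 0.49, size=n_lowq)
        # poorly imputed dosages are noisy, continuous versions of the truth
        noise = rng.normal(0.0, 0.4, size=(n, n_lowq))
        X[:, lowq_idx] = np.clip(X[:, lowq_idx] + noise, 0.0, 2.0)

    call_rate = np.ones(m)
    n_lowcr = int(round(config.frac_low_callrate * m))
    if n_lowcr:
        lowcr_idx = rng.choice(m, size=n_lowcr, replace=False)
        call_rate[lowcr_idx] = rng.uniform(0.80, 0.94, size=n_lowcr)
        for j, cr in zip(lowcr_idx, call_rate[lowcr_idx]):
            miss = rng.random(n) > cr
            X[miss, j] = np.nan

    af = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    hwe = np.array([_hwe_p(X[:, j]) for j in range(m)])
    empirical_cr = 1.0 - np.isnan(X).mean(axis=0)
    gm = GenotypeMatrix(
        X,
        variant_ids=np.array([f"rs{j:07d}" for j in range(m)]),
        subject_ids=np.array([f"S{i:05d}" for i in range(n)]),
        maf=maf, rsq=rsq, hwe_p=hwe, call_rate=empirical_cr,
    )
    gm.true_af = freq  # drawn generative frequencies, for recovery checks
    return gm


def generate_covariates(config: SimulationConfig, n: int | None = None,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Age (z-scored around a 65 y mean) , sex, and an independent ICV column."""
    n = n or config.n_subjects
    rng = rng or config.rng(stream=2)
    age_years = rng.normal(65.0, 8.0, size=n)
    return pd.DataFrame({
        "age": (age_years - age_years.mean()) / age_years.std(ddof=1),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "icv": rng.normal(0.0, 1.0, size=n),
    })


# ---------------------------------------------------------------------------
# phenotypes


def _standardized_dosages(g: GenotypeMatrix) -> np.ndarray:
    X = g.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    p = X.mean(axis=0) / 2.0
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("monomorphic variants present; run QC first")
    return (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def simulate_vertex_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig,
                               positions: np.ndarray | None = None,
                               covariates: pd.DataFrame | None = None,
                               h2_true: np.ndarray | None = None,
                               ) -> tuple[ShapeMeasureMatrix, GroundTruth]:
    """Vertex phenotypes y_v = covariates . slopes + genetic_v + residual_v.

    The genetic value at vertex v is Z w_v with w_v ~ N(0, h2_v / M) per
    variant (infinitesimal architecture); the residual has variance
    1 - h2_v, so each column has unit variance in expectation and h^2_v is
    the genetic variance share.
    """
    Z = _standardized_dosages(genotypes)
    n, m = Z.shape
    if h2_true is None:
        h2_true = h2_field(config, positions)
    h2_true = np.asarray(h2_true, dtype=float)
    if ((h2_true < 0) | (h2_true >= 1)).any():
        raise ValueError("true h2 must lie in [0, 1) at every vertex")
    V = len(h2_true)
    rng = config.rng(stream=3)
    W = rng.normal(0.0, 1.0, size=(m, V)) / np.sqrt(m)
    G = (Z @ W) * np.sqrt(h2_true)[None, :]
    E = rng.normal(0.0, 1.0, size=(n, V)) * np.sqrt(1.0 - h2_true)[None, :]
    if covariates is None:
        covariates = generate_covariates(config, n=n)
    fixed = np.zeros((n, V))
    slopes = dict(config.covariate_effects)
    for name, beta in slopes.items():
        if name not in covariates.columns:
            raise ValueError(f"covariate_effects names unknown column {name!r}")
        fixed += beta * covariates[name].to_numpy(float)[:, None]
    Y = fixed + G + E
    gt = GroundTruth(h2_true=h2_true, slopes=slopes, genetic_values=G,
                     covariates=covariates, phenotypes=Y)
    return (ShapeMeasureMatrix(Y, measure="score", subject_ids=genotypes.subject_ids), gt)


# ---------------------------------------------------------------------------
# twins


def generate_twin_cohort(config: SimulationConfig, n_vertices: int | None = None,
                         ) -> tuple[TwinCohort, GroundTruth]:
    """MZ/DZ/OS twin pairs with additive ACE structure.

    Scalar mode (``n_vertices=None``) draws a single phenotype per member
    with variance fractions (a2, c2) from the config; vertex-wise mode uses
    the h^2 field as the per-vertex a^2 with constant c^2.  MZ pairs share
    the genetic value fully, DZ and opposite-sex pairs with correlation
    one half; shared environment is common to both members, sex differs
    within OS pairs.
    """
    rng = config.rng(stream=4)
    n_mz, n_dz, n_os = config.mz_pairs, config.dz_pairs, config.os_pairs
    n_pairs = n_mz + n_dz + n_os
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * n_dz + ["OS"] * n_os)
    if n_vertices is None:
        a2_v = np.array([config.a2])
    else:
        cfg_v = config.n_vertices
        a2_v = h2_field(config) if n_vertices == cfg_v else np.clip(
            h2_field(SimulationConfig(**{**asdict(config), "n_vertices": n_vertices})),
            0.0, 1.0 - config.c2 - 1e-6)
    c2 = config.c2
    e2_v = 1.0 - a2_v - c2
    V = len(a2_v)

    is_mz = zyg == "MZ"
    shared = rng.normal(size=(n_pairs, V))
    indep = rng.normal(size=(n_pairs, V))
    A1 = shared
    A2 = np.where(is_mz[:, None], shared, 0.5 * shared + np.sqrt(0.75) * indep)
    C = rng.normal(size=(n_pairs, V))
    E1 = rng.normal(size=(n_pairs, V))
    E2 = rng.normal(size=(n_pairs, V))
    sa = np.sqrt(a2_v)[None, :]
    sc = np.sqrt(c2)
    se = np.sqrt(e2_v)[None, :]
    y1 = sa * A1 + sc * C + se * E1
    y2 = sa * A2 + sc * C + se * E2

    age = rng.normal(0.0, 1.0, size=n_pairs)
    sex1 = rng.integers(0, 2, size=n_pairs).astype(float)
    sex2 = np.where(zyg == "OS", 1.0 - sex1, sex1)
    cov1 = pd.DataFrame({"age": age, "sex": sex1})
    cov2 = pd.DataFrame({"age": age, "sex": sex2})
    slopes = dict(config.covariate_effects)
    for name, beta in slopes.items():
        y1 += beta * cov1[name].to_numpy(float)[:, None]
        y2 += beta * cov2[name].to_numpy(float)[:, None]

    if n_vertices is None:
        y1, y2 = y1[:, 0], y2[:, 0]
        a2_out: float | np.ndarray = float(a2_v[0])
        e2_out: float | np.ndarray = float(e2_v[0])
    else:
        a2_out, e2_out = a2_v, e2_v
    cohort = TwinCohort(y1, y2, zyg, covariates1=cov1, covariates2=cov2)
    gt = GroundTruth(h2_true=np.atleast_1d(a2_v), slopes=slopes,
                     a2=a2_out, c2=c2, e2=e2_out)
    return cohort, gt


# ---------------------------------------------------------------------------
# meshes


def make_template(n_vertices: int = 1937, radius: float = 10.0,
                  elongation: float = 3.0, structure: str = "structure",
                  hemisphere: str = "left") -> SurfaceMesh:
    """Closed, outward-oriented, elongated ellipsoid with ~n_vertices vertices.

    A UV parameterization (rings of longitude between two pole vertices)
    gives exact control of topology; the z-axis is stretched by
    ``elongation`` so a medial curve is well defined.
    """
    n_lon = max(8, int(round(np.sqrt(2.0 * n_vertices))))
    n_lat = max(3, int(round((n_vertices - 2) / n_lon)))
    thetas = np.linspace(0.0, np.pi, n_lat + 2)[1:-1]
    phis = np.linspace(0.0, 2.0 * np.pi, n_lon, endpoint=False)
    verts = [np.array([0.0, 0.0, radius * elongation])]
    for th in thetas:
        for ph in phis:
            verts.append(np.array([radius * np.sin(th) * np.cos(ph),
                                   radius * np.sin(th) * np.sin(ph),
                                   radius * elongation * np.cos(th)]))
    verts.append(np.array([0.0, 0.0, -radius * elongation]))
    verts = np.asarray(verts)
    top, bottom = 0, len(verts) - 1

    def ring(i, j):  # vertex index of ring i (0-based), longitude j
        return 1 + i * n_lon + (j % n_lon)

    faces = []
    for j in range(n_lon):  # top cap fan
        faces.append([top, ring(0, j), ring(0, j + 1)])
    for i in range(n_lat - 1):
        for j in range(n_lon):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    for j in range(n_lon):  # bottom cap fan
        faces.append([bottom, ring(n_lat - 1, j + 1), ring(n_lat - 1, j)])
    mesh = SurfaceMesh(verts, np.asarray(faces), structure=structure, hemisphere=hemisphere)
    # orient outward (positive signed volume)
    v, f = mesh.vertices, mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0
    if signed < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
    return mesh


def _radial_directions(template: SurfaceMesh, curve: MedialCurve
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Outward unit directions from the medial curve, and the distances."""
    dist, feet = nearest_curve_points(template.vertices, curve)
    vec = template.vertices - feet
    safe = np.maximum(dist, 1e-9)[:, None]
    return vec / safe, dist


def generate_shape_cohort(config: SimulationConfig,
                          phenotypes: ShapeMeasureMatrix | np.ndarray | None = None,
                          genotypes: GenotypeMatrix | None = None,
                          structure: str = "structure",
                          ) -> tuple[list[SurfaceMesh], SurfaceMesh, GroundTruth]:
    """Subject meshes displacing the template radially by the phenotypes.

    Vertex v of subject i sits at template_v + d * y_iv * u_v, with u_v the
    outward direction from the template medial curve and d the mm-per-unit
    displacement amplitude.  Displacements larger than 80% of the local
    template radius are clamped (with a warning) to keep meshes from
    self-intersecting.  Returns (meshes, template, ground truth).
    """
    template = make_template(config.n_vertices, structure=structure)
    V = template.n_vertices
    curve = fit_medial_curve(template)
    dirs, base_dist = _radial_directions(template, curve)
    if phenotypes is None:
        if genotypes is None:
            genotypes = generate_genotypes(config)
        pheno, gt = simulate_vertex_phenotypes(
            genotypes, config, h2_true=h2_field(config, positions=template.vertices))
        Y = pheno.values
    else:
        Y = phenotypes.values if isinstance(phenotypes, ShapeMeasureMatrix) else np.asarray(phenotypes, float)
        if Y.shape[1] != V:
            raise ValueError(f"phenotypes have {Y.shape[1]} vertices, template has {V}")
        gt = GroundTruth(phenotypes=Y)
    disp = config.displacement_mm * Y
    limit = 0.8 * base_dist[None, :]
    if (np.abs(disp) > limit).any():
        n_clamped = int((np.abs(disp) > limit).sum())
        warnings.warn(f"{n_clamped} vertex displacements clamped to 80% of the local "
                      "radius to avoid self-intersection", stacklevel=2)
        disp = np.clip(disp, -limit, limit)
    meshes = [SurfaceMesh(template.vertices + disp[i][:, None] * dirs,
                          template.faces, structure=structure)
              for i in range(len(disp))]
    return meshes, template, gt


def generate_rescan(cohort: list[SurfaceMesh], config: SimulationConfig,
                    template: SurfaceMesh | None = None,
                    ground_truth: GroundTruth | None = None,
                    stream: int = 5) -> list[SurfaceMesh]:
    """One re-measured mesh set: independent per-vertex radial measurement noise.

    Call twice (with different ``stream`` values) for a scan/rescan pair.
    The implied true ICC, sigma_b^2 / (sigma_b^2 + sigma_n^2) with
    sigma_b^2 the cohort's between-subject variance of the radial
    displacement, is recorded on ``ground_truth`` when given.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if template is None:
        template = make_template(config.n_vertices)
    curve = fit_medial_curve(template)
    dirs, _ = _radial_directions(template, curve)
    sd_pheno = noise_field(config, positions=template.vertices)
    sd_mm = config.displacement_mm * sd_pheno
    rng = config.rng(stream=stream)
    out = []
    for m in cohort:
        noise = rng.normal(0.0, 1.0, size=m.n_vertices) * sd_mm
        out.append(SurfaceMesh(m.vertices + noise[:, None] * dirs, m.faces,
                               structure=m.structure, hemisphere=m.hemisphere))
    if ground_truth is not None:
        if ground_truth.phenotypes is not None:
            var_b = (config.displacement_mm ** 2
                     * ground_truth.phenotypes.var(axis=0, ddof=1))
        else:
            var_b = config.displacement_mm ** 2 * np.ones(template.n_vertices)
        ground_truth.icc_true = var_b / (var_b + sd_mm ** 2)
    return out
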