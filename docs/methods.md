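# Methods

## Scope and data model

The package analyzes *corresponded* triangle meshes: every subject's mesh
for a given structure has the same topology, so vertex v is anatomically
matched across subjects. Establishing that correspondence (surface
registration) is outside the package; it is the entry contract. All
coordinates are in millimetres.

## Shape descriptors

**Medial curve.** For an elongated structure, vertices are projected onto
the first principal axis of the vertex cloud, partitioned into equal-width
bins over the inner [2%, 98%] of the axial extent, and the per-bin
centroids, smoothed with a 3-point moving average, form an ordered
polyline. Two refinement passes re-bin the vertices by arc-length position
along the current curve, which makes the slabs perpendicular to the local
centerline and matters for bent structures. Bins with fewer than three
vertices merge with a neighbor — a lone tip vertex would otherwise place
the curve on the surface itself and zero the radial distance there. The
axial projection is quantized at 1e-9 of the extent so symmetric vertex
rings, identical up to round-off, never straddle a bin edge. A mesh whose
top two covariance eigenvalues differ by less than a factor 1.5 is
rejected: a near-spherical shape has no unique long axis. The curve is
fitted once, on the template, and reused for all subjects, so radial
distance differences reflect surface change rather than curve refitting.

**Radial distance** is the Euclidean distance from a vertex to the nearest
point of the piecewise-linear medial curve (always ≥ 0).

**Log-Jacobian** is ln(A_subject(v) / A_template(v)) where A(v) is the
barycentric one-ring area: one third of the summed incident triangle
areas. It is an area (surface-dilation) Jacobian, not a volumetric one;
uniform scaling by s yields exactly 2 ln s. Zero-area template one-rings
are an error naming the vertex.

**Gross volume** uses the signed-tetrahedron divergence sum over the
closed mesh, in the mesh's native units cubed (mm³); reporting code
converts to cm³. Inward orientation is auto-corrected with a logged
warning; open meshes are an error.

All three descriptors are invariant under a common rigid motion of subject
and template (curve refitted), verified to 1e-8 in the tests.

## Population heritability (GRM / ReML)

Variant QC retains dosages with MAF ≥ 0.01, imputation R² ≥ 0.5,
Hardy–Weinberg P ≥ 1e-6 and call rate ≥ 0.95. The GRM is
K = WW′/M with w_ij = (x_ij − 2p_j)/√(2p_j(1−p_j)), allele frequencies
estimated from the analysis sample, and missing dosages mean-imputed per
variant. Relatedness pruning greedily removes, while any pair exceeds the
threshold, the subject in the most offending pairs (ties: lowest index).
The default threshold is 0.025; the pipeline raises it to
max(0.025, 6/√M) because off-diagonal GRM entries of truly unrelated pairs
have sampling s.d. ≈ 1/√M, and at desk-scale M the 0.025 rule — which
presumes genome-scale marker counts — would discard most of a simulated
cohort as false-positive relatives.

Phenotypes are residualized on a named covariate design — `basic`
(intercept, age, sex), `icv` (+ intracranial volume) or `volume` (+ the
structure's gross volume) — then variance-standardized, so h² estimates
are variance fractions. With K = U diag(λ) U′ computed once per cohort,
the model y ~ N(0, σ²(h²K + (1−h²)I)) has, after rotation ỹ = U′y, the
profile −2 log-likelihood

    ℓ(h²) = Σᵢ log dᵢ + n log( (1/n) Σᵢ ỹᵢ²/dᵢ ),   dᵢ = h²(λᵢ−1) + 1,

which is one-dimensional in h² and maximized on [0, 1] by a coarse grid
(101 points) plus golden-section refinement to 1e-6, vectorized across
phenotype columns. Fixed effects are projected out before rotation and
their degrees of freedom ignored in the rotated likelihood — an
approximation that is accurate for small covariate counts. Estimates are
clamped to [0, 1] with boundary solutions reported, not suppressed.
Standard errors come from the numerical curvature of the profile at the
optimum (NaN when the profile is flat at a boundary). The null h² = 0 sits
on the parameter boundary, so the LRT is referred to ½χ²₀ + ½χ²₁: p = 1
when the statistic is 0, else ½·P(χ²₁ > LRT). An identity-like GRM (all
eigenvalues equal) leaves the decomposition unidentified; the estimator
then returns h² = 0, p = 1 with a warning rather than an arbitrary split.
Tiny negative eigenvalues within −1e-6·λmax are clipped to zero; anything
more negative is an error advising pruning or regularization.

The Haseman–Elston fast path regresses phenotype products yᵢyⱼ on Kᵢⱼ over
all pairs i < j; with standardized phenotypes the slope estimates h²
directly. The raw (unclamped) slope is kept alongside the clamped value
for unbiased cross-estimator comparison. The permutation check recomputes
the ReML LRT under random subject permutations, with the add-one rule
p = (1 + #{perm ≥ obs})/(1 + n_perm), so p is never exactly 0.

## Twin heritability (ACE)

Pairs are MZ, DZ, or opposite-sex (OS); OS pairs are pooled with DZ
(genetic correlation ½) with sex as a covariate, since the additive model
gives them the same expected covariance. Covariates are residualized from
both members jointly, then the phenotype is standardized, so variance
fractions satisfy a² + c² + e² = 1 and the pair log-likelihood is a sum of
bivariate normal densities with correlation a²·(1 or ½) + c². The ML fit
uses SLSQP with nonnegativity bounds and the simplex constraint, started
from the Falconer point (clamped into the simplex) plus three seeded
random restarts. The a² = 0 null profile is a 1-D bounded optimization in
c²; the LRT again uses the ½χ²₀ + ½χ²₁ boundary mixture. Falconer's
estimates h² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ are computed from
double-entered pair correlations and reported unclamped.

This is a residualize-then-fit scheme, not joint fixed-effect ML; the two
differ only in covariate degrees of freedom, negligible at hundreds of
pairs. Dominance (ADE) models and extended pedigrees are out of scope.

## Reproducibility (ICC)

The default reliability index is the two-way random-effects,
absolute-agreement, single-measurement ICC(2,1) from the per-vertex
subjects × sessions ANOVA mean squares with k = 2 sessions; the one-way
ICC(1,1) is available via a flag. The form had to be chosen — the
convention is not dictated by the analysis — and absolute agreement was
preferred because a systematic session shift is a real reproducibility
failure. Negative estimates are retained (clamping would bias reliability
summaries upward); vertices with zero between-subject variance return NaN
and are excluded from concordance with a logged count. Concordance between
an h² map and an ICC map reports Pearson and Spearman correlations over
the defined vertices plus the paired table.

## PCA reduction

Per structure and measure, a full PCA of the centered measure matrix
(covariance convention — the measures share units within a structure)
yields min(n_subjects − 1, n_vertices) components, eigenvalues descending,
with each loading vector's largest-magnitude entry forced positive so runs
are comparable. Orthonormality and variance conservation are asserted on
every call. Component scores are then treated as phenotypes for the same
ReML machinery. The rank agreement between eigenvalue order and
heritability order is a tie-corrected Spearman ρ. Measures are reduced
raw-centered, with covariate adjustment applied to the component scores
afterward.

## FDR

Benjamini–Hochberg step-up at q = 0.05 (statsmodels backend), pooled
across all vertices and structures of one measure by default, with a
per-structure mode in the config. The pooled default treats the whole
brain map of one measure as one family.

## Synthetic cohorts

The generators emulate the statistical structure the estimators assume:

* **Genotypes** — unlinked dosages from Binomial(2, p) with p uniform on
  [0.05, 0.5]; a configurable fraction of variants is rare (p < 0.01), a
  fraction carries imputation R² < 0.5 with correspondingly noisy
  continuous dosages, and a fraction has reduced call rate — so every QC
  filter has genuine work. HWE p-values are computed from hard-called
  genotype counts.
* **Vertex phenotypes** — y_v = covariates·slopes + g_v + e_v with g_v a
  weighted sum of standardized dosages, per-variant weights of variance
  h²_v/M (infinitesimal architecture: all variants causal), and residual
  variance 1 − h²_v, so columns have unit variance in expectation and h²
  is the genetic share. The true h² field is a sum of Gaussian bumps
  (default peaks 0.533 and 0.35), evaluated in vertex-index space or on
  template coordinates.
* **Twins** — members share the genetic value fully (MZ) or with
  correlation ½ (DZ/OS) plus a common shared-environment term; the default
  design is 148 MZ + 120 DZ + 82 OS pairs. OS pairs differ in sex.
* **Meshes** — an elongated UV-parameterized ellipsoid template
  (z-stretch 3:1, ~1,937 vertices by default to match a realistic
  per-structure vertex count) displaced radially — along the direction
  from the template medial curve to the vertex — by
  0.5 mm per phenotype unit. Displacements beyond 80% of the local radius
  are clamped with a warning to prevent self-intersection.
* **Rescans** — each call to the rescan generator returns one re-measured
  mesh set with independent per-vertex radial noise from the noise field
  (default: 0.5 baseline s.d. with one poorly-reproducible patch at
  s.d. 2); two calls give a scan/rescan pair, and the implied true ICC
  σ²_b/(σ²_b + σ²_n) is recorded with the ground truth. In the pipeline
  every analyzed scan carries measurement noise, so poor reproducibility
  depresses estimated heritability exactly as it would in acquired data.

Every generator is fully determined by the config seed (per-purpose
substreams derived via SeedSequence).

What the synthetic cohorts do **not** emulate: linkage disequilibrium and
population structure in the genotypes, non-additive genetic effects,
tangential (non-radial) shape deformation, registration/segmentation
failure modes, and age- or disease-dependent heritability. Passing tests
therefore demonstrate the correctness and calibration of the estimators
under their assumed models — not robustness to the violations real imaging
genetics data can present.

## Validation studies and sizes

`shapeherit.benchmarks` holds the designed studies; the test suite asserts
bounds on their outputs and `scripts/acceptance.py` reports them. Chosen
sizes balance sampling error against one-CPU runtime:

* GRM vs brute force: 20 random instances with n ≤ 10, M ≤ 20, agreement
  to 1e-12 (measured: machine epsilon).
* Recovery: n = 2,000 unrelated, M = 5,000 variants, 50 replicate
  phenotypes at h² ∈ {0, 0.25, 0.5, 0.8}; per-replicate sampling s.d. is
  ≈ √(2M)/n ≈ 0.05, so the mean over 50 replicates isolates bias. At
  h² = 0 the [0,1] clamp makes the mean estimate slightly positive
  (≈ 0.016), which is the expected boundary effect, not bias in the
  interior.
* Null calibration: n = 500, M = 1,000, 1,000 null phenotypes for the
  parametric type-I error; 300 phenotypes × 199 permutations for the
  permutation cross-check. Calibration is a size property, so the smaller
  n keeps the runtime in seconds without weakening the check.
* Twin recovery: 100 replicates at the 350-pair design.
* Map properties: one n = 800 cohort for the reliability-gating and
  covariate-model studies; the eigenvalue-vs-h² rank study uses n = 2,000
  because at smaller n the smallest-variance components couple weakly to
  the realized genetic noise and the rank correlation sits measurably
  above its asymptotic near-zero value.
* FDR: 10 replicate maps of 60 null + 40 signal (h² = 0.5) vertices;
  BH controls the false-discovery proportion at π₀q = 0.03 here.

## Numerical conventions

Grid-plus-golden-section likelihood search to 1e-6 in h²; SLSQP ftol 1e-10
for ACE; GRM symmetrized after the matrix product; float32 lower-triangle
storage in the GCTA-dialect GRM files; TSV outputs carry a commented
header with version, seed and config hash. The per-structure report lists
gross-volume h², the maximal vertex-wise h² per measure, and the maximal
component h² per measure, with p-values; maxima over many noisy estimates
are upward-biased at small n, which is why the worked example's maxima sit
slightly above the true field peak.

## Known limitations

Heritability s.e. from profile curvature is unavailable exactly at flat
boundaries (reported NaN); the ACE map currently reports no per-vertex
s.e.; the medial curve is a simplified axis construction, not a full
medial-surface model, so radial distance on strongly curved or branching
structures inherits its bias; and the greedy pruning heuristic does not
guarantee the maximum unrelated subset.
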