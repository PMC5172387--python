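# shapeherit

Genetic contributions to the **shape** of subcortical brain structures,
estimated vertex by vertex. The package implements the full analysis chain
for corresponded surface meshes of structures such as the hippocampus,
caudate or thalamus:

1. **Shape descriptors** — for each vertex of a corresponded mesh, the
   *radial distance* (distance, in mm, to the structure's medial curve) and
   the *log-Jacobian* (natural log of the local one-ring area ratio between
   subject and template, a surface-dilation measure), plus gross volume via
   the signed-tetrahedron formula.
2. **Population heritability** — narrow-sense h² per vertex from a genomic
   relationship matrix (GRM) of unrelated individuals, by exact single-GRM
   restricted maximum likelihood under y ~ N(0, σg²K + σe²I), with a
   Haseman–Elston moment estimator as fast cross-check and a permutation
   test as a nonparametric check on the parametric p-values. Significance
   of h² > 0 uses the boundary likelihood-ratio test referred to the
   mixture ½χ²₀ + ½χ²₁.
3. **Twin heritability** — ACE maximum likelihood on MZ/DZ/opposite-sex
   pairs (pair covariance a² + c² for MZ, a²/2 + c² for DZ/OS), with
   Falconer's h² = 2(r_MZ − r_DZ) as initializer, and the same
   boundary-mixture LRT.
4. **Reproducibility** — per-vertex scan–rescan ICC(2,1) maps and their
   concordance with the heritability maps.
5. **Reduction** — full PCA per structure and measure, heritability of the
   component scores, and the rank agreement between eigenvalue order and
   heritability order.
6. **Multiple testing** — Benjamini–Hochberg FDR at q = 0.05, pooled across
   vertices and structures per measure (or per structure).

Because real cohorts of this kind are not openly distributable, the package
ships a first-class synthetic-cohort module (`shapeherit.simulate`) that
generates genotype dosages with QC metadata, vertex phenotypes with a
smooth spatial h² field, twin pairs with exact ACE structure, corresponded
meshes carrying the phenotypes as radial displacements, and rescans with a
spatially varying noise floor — all with stored ground truth, so every
stage of the pipeline is testable end to end.

## Worked example

```python
import shapeherit as sh

cfg = sh.AnalysisConfig(
    out_dir="demo_out", seed=1,
    structures=("left_hippocampus", "left_caudate"),
    simulation=sh.SimulationConfig(n_subjects=800, n_variants=2000,
                                   n_vertices=150, seed=1))
bundle = sh.run_pipeline(cfg)
print(bundle["report"].round(3).to_string(index=False))
```

prints (seed 1):

```
       structure  volume_h2  volume_p  max_h2_radial_distance  max_p_radial_distance  max_h2_log_jacobian  max_p_log_jacobian  max_h2_pca_radial_distance  max_h2_pca_log_jacobian
left_hippocampus      0.211     0.002                   0.489                    0.0                0.334                 0.0                       0.321                    0.294
    left_caudate      0.215     0.003                   0.545                    0.0                0.373                 0.0                       0.400                    0.210
```

Reading the table: the simulated h² field peaks at 0.533, and the maximal
vertex-wise estimates (0.49–0.55 for radial distance) land near it, while
gross volume — an aggregate over the whole surface — is far less heritable
(≈ 0.21), and the best PCA component is less heritable than the best
vertex: spatially localized genetic effects are diluted by aggregation.
The bundle also carries ICC maps and their concordance with heritability
(here Pearson r = 0.437, p = 1.3e-08 for left hippocampal radial
distance: poorly measured vertices cannot show heritability) and
ground-truth recovery correlations (0.73 / 0.64 between estimated and true
h² fields at this cohort size).

The same stages are scriptable from the shell:

```bash
shapeherit run --seed 1 --out-dir demo_out
shapeherit simulate --out dosages.tsv --n-subjects 500 --n-variants 2000
shapeherit grm --dosages dosages.tsv --out-prefix mygrm --prune 0.15
shapeherit fdr --pvalues pvals.txt --q 0.05 --out flags.tsv
```

## Layout

```
src/shapeherit/
  simulate.py     synthetic cohorts with ground truth
  mesh.py         surface meshes, medial curves, shape descriptors, volume
  genotypes.py    variant QC, GRM construction (incl. GCTA binary dialect),
                  relatedness pruning
  population.py   covariate models, residualization, ReML + HE heritability,
                  permutation p, vertex-wise maps
  twin.py         twin cohorts, Falconer, ACE maximum likelihood, twin maps
  reliability.py  ICC(2,1)/ICC(1,1) maps, concordance, map correlations
  reduction.py    full PCA, component heritability, rank agreement
  fdr.py          Benjamini–Hochberg step-up
  pipeline.py     end-to-end orchestration and per-structure report
  benchmarks.py   designed simulation studies used for validation
  cli.py          `shapeherit` command-line interface
```

See `docs/methods.md` for the statistical models, default parameters, and
the limits of what the synthetic cohorts can demonstrate.
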