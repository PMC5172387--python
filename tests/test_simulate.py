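"""Generators: determinism, moment checks, and designed QC failures."""

import numpy as np
import pytest

import shapeherit as sh
from shapeherit.simulate import h2_field, noise_field


def test_genotypes_deterministic_by_seed():
    cfg = sh.SimulationConfig(n_subjects=4, n_variants=3, n_vertices=5, seed=1)
    a = sh.generate_genotypes(cfg)
    b = sh.generate_genotypes(cfg)
    assert np.array_equal(a.dosages, b.dosages, equal_nan=True)
    assert np.array_equal(a.maf, b.maf)


def test_allele_frequency_recovery_within_sampling_error():
    cfg = sh.SimulationConfig(n_subjects=10_000, n_variants=50, n_vertices=5, seed=2,
                              frac_rare=0.0, frac_low_quality=0.0, frac_low_callrate=0.0)
    g = sh.generate_genotypes(cfg)
    p = g.true_af
    mean_dosage = g.dosages.mean(axis=0)
    se = np.sqrt(2.0 * p * (1.0 - p) / cfg.n_subjects)
    assert np.all(np.abs(mean_dosage - 2.0 * p) < 3.0 * se)


def test_qc_failures_are_generated_and_filterable():
    cfg = sh.SimulationConfig(n_subjects=500, n_variants=1000, n_vertices=5, seed=3)
    g = sh.generate_genotypes(cfg)
    assert (g.rsq < 0.5).sum() > 0
    assert (g.maf < 0.01).sum() > 0
    qc = sh.filter_variants(g)
    assert qc.n_variants < g.n_variants
    assert (qc.rsq >= 0.5).all() and (qc.maf >= 0.01).all()


def test_phenotypes_unit_variance_and_null_field(small_cohort):
    cfg, qc = small_cohort["config"], small_cohort["qc"]
    y, gt = sh.simulate_vertex_phenotypes(qc, cfg, h2_true=np.zeros(30))
    # null field: phenotypes independent of genotypes
    assert np.all(gt.h2_true == 0)
    assert np.allclose(gt.genetic_values, 0.0)
    var = y.values.var(axis=0, ddof=1)
    assert abs(var.mean() - 1.0) < 0.15  # unit scale up to covariate share


def test_phenotype_genetic_variance_matches_field(small_cohort):
    cfg, qc = small_cohort["config"], small_cohort["qc"]
    h2 = np.linspace(0.0, 0.8, 40)
    y, gt = sh.simulate_vertex_phenotypes(qc, cfg, h2_true=h2)
    gvar = gt.genetic_values.var(axis=0, ddof=1)
    # realized genetic variance tracks the target h2 field
    assert np.corrcoef(gvar, h2)[0, 1] > 0.95


def test_h2_field_has_bumpy_clusters():
    cfg = sh.SimulationConfig(n_subjects=10, n_variants=10, n_vertices=200, seed=0)
    f = h2_field(cfg)
    assert f.max() > 0.5 and f.min() < 0.01
    assert ((f >= 0) & (f < 1)).all()


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        sh.SimulationConfig(n_subjects=0)
    with pytest.raises(ValueError):
        sh.SimulationConfig(a2=0.7, c2=0.4)
    with pytest.raises(ValueError):
        sh.SimulationConfig(h2_field_spec=((0, 5.0, 0.9),), c2=0.2)
    with pytest.raises(ValueError):
        sh.SimulationConfig(noise_field_spec={"baseline": -1.0})


def test_twin_pair_correlations_match_ace_expectations():
    cfg = sh.SimulationConfig(n_subjects=10, mz_pairs=10_000, dz_pairs=10_000,
                              os_pairs=1, a2=0.6, c2=0.2, seed=4,
                              covariate_effects={})
    cohort, gt = sh.generate_twin_cohort(cfg)
    mz = cohort.is_mz
    r_mz = np.corrcoef(cohort.y1[mz], cohort.y2[mz])[0, 1]
    dz = cohort.zygosity == "DZ"
    r_dz = np.corrcoef(cohort.y1[dz], cohort.y2[dz])[0, 1]
    se = 1.0 / np.sqrt(10_000)
    assert abs(r_mz - 0.8) < 3 * se * (1 - 0.8 ** 2)
    assert abs(r_dz - 0.5) < 3 * se * (1 - 0.5 ** 2)


def test_twin_null_independence():
    cfg = sh.SimulationConfig(n_subjects=10, mz_pairs=5000, dz_pairs=5000, os_pairs=1,
                              a2=0.0, c2=0.0, seed=5, covariate_effects={})
    cohort, _ = sh.generate_twin_cohort(cfg)
    mz = cohort.is_mz
    assert abs(np.corrcoef(cohort.y1[mz], cohort.y2[mz])[0, 1]) < 0.05
    assert abs(np.corrcoef(cohort.y1[~mz], cohort.y2[~mz])[0, 1]) < 0.05


def test_twin_default_design_mix():
    cfg = sh.SimulationConfig(n_subjects=10)
    cohort, _ = sh.generate_twin_cohort(cfg)
    assert cohort.n_pairs == 350
    counts = {z: int((cohort.zygosity == z).sum()) for z in ("MZ", "DZ", "OS")}
    assert counts == {"MZ": 148, "DZ": 120, "OS": 82}
    # opposite-sex pairs differ in sex, same-sex pairs do not
    os_mask = cohort.zygosity == "OS"
    assert np.all(cohort.covariates1["sex"][os_mask] != cohort.covariates2["sex"][os_mask])
    assert np.all(cohort.covariates1["sex"][~os_mask] == cohort.covariates2["sex"][~os_mask])


def test_shape_cohort_contract_and_displacement():
    cfg = sh.SimulationConfig(n_subjects=100, n_variants=60, n_vertices=80, seed=6,
                              covariate_effects={})
    # zero displacement -> identical meshes
    zeros = np.zeros((3, sh.make_template(80).n_vertices))
    meshes, template, _ = sh.generate_shape_cohort(cfg, phenotypes=zeros)
    for m in meshes:
        assert np.allclose(m.vertices, template.vertices)
    # +1 mm at one vertex raises its radial distance by about 1 mm
    one = np.zeros((1, template.n_vertices))
    j = template.n_vertices // 2
    one[0, j] = 1.0 / cfg.displacement_mm  # phenotype units for 1 mm
    meshes1, template, _ = sh.generate_shape_cohort(cfg, phenotypes=one)
    curve = sh.fit_medial_curve(template)
    d0 = sh.radial_distance(template, curve)
    d1 = sh.radial_distance(meshes1[0], curve)
    assert abs((d1[j] - d0[j]) - 1.0) < 0.01
    # 100 subjects -> 100 measure rows
    meshes, template, _ = sh.generate_shape_cohort(cfg)
    mm = sh.measure_cohort(meshes, template, measure="radial_distance")
    assert mm.n_subjects == 100


def test_rescan_noiseless_and_variance_ratio():
    cfg = sh.SimulationConfig(n_subjects=30, n_variants=60, n_vertices=60, seed=7,
                              noise_field_spec={"baseline": 0.0}, covariate_effects={})
    meshes, template, gt = sh.generate_shape_cohort(cfg)
    s1 = sh.generate_rescan(meshes, cfg, template=template, ground_truth=gt, stream=21)
    s2 = sh.generate_rescan(meshes, cfg, template=template, stream=22)
    for a, b in zip(s1, s2):
        assert np.allclose(a.vertices, b.vertices)
    assert np.allclose(gt.icc_true, 1.0)
    m1 = sh.measure_cohort(s1, template)
    m2 = sh.measure_cohort(s2, template)
    assert np.allclose(sh.icc(m1, m2).values, 1.0)


def test_rescan_records_closed_form_icc():
    # sigma_b^2 = 3 sigma_n^2 at every vertex -> true ICC 0.75
    cfg = sh.SimulationConfig(n_subjects=20, n_variants=60, n_vertices=40, seed=8,
                              covariate_effects={}, displacement_mm=1.0,
                              noise_field_spec={"baseline": 1.0})
    V = sh.make_template(40).n_vertices
    rng = np.random.default_rng(0)
    pheno = rng.normal(0.0, np.sqrt(3.0), size=(20, V))
    meshes, template, gt = sh.generate_shape_cohort(cfg, phenotypes=pheno)
    gt.phenotypes = pheno
    sh.generate_rescan(meshes, cfg, template=template, ground_truth=gt)
    sigma_b2 = pheno.var(axis=0, ddof=1)
    expected = sigma_b2 / (sigma_b2 + 1.0)
    assert np.allclose(gt.icc_true, expected)
    assert abs(np.median(gt.icc_true) - 0.75) < 0.1


def test_noise_field_patch_raises_local_sd():
    cfg = sh.SimulationConfig(n_subjects=10, n_variants=10, n_vertices=100, seed=0)
    sd = noise_field(cfg)
    assert sd.max() > 3 * sd.min()


def test_config_yaml_round_trip(tmp_path):
    cfg = sh.SimulationConfig(n_subjects=10, n_variants=20, n_vertices=30, seed=9,
                              h2_field_spec=((5, 3.0, 0.4),))
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert sh.SimulationConfig.from_yaml(path) == cfg
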