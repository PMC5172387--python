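"""GRM/ReML and Haseman–Elston heritability: oracles and edge cases."""

import numpy as np
import pandas as pd
import pytest

import shapeherit as sh
from shapeherit.population import _check_eig, reml_h2_many


@pytest.fixture(scope="module")
def cohort():
    cfg = sh.SimulationConfig(n_subjects=500, n_variants=1000, n_vertices=20, seed=11,
                              covariate_effects={})
    qc = sh.filter_variants(sh.generate_genotypes(cfg))
    grm = sh.compute_grm(qc)
    return cfg, qc, grm


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        Y = rng.normal(5.0, 1.0, size=(50, 3))
        model = sh.CovariateModel("const", np.ones((50, 1)))
        R = sh.residualize(Y, model)
        assert np.allclose(R.mean(axis=0), 0.0, atol=1e-12)

    def test_perfect_fit_gives_zero_residual(self, rng):
        age = rng.normal(size=80)
        cov = pd.DataFrame({"age": age, "sex": rng.integers(0, 2, 80).astype(float)})
        model = sh.make_design(cov, "basic")
        y = 1.0 + 2.5 * age
        assert np.allclose(sh.residualize(y, model), 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        cov = pd.DataFrame({"age": rng.normal(size=100),
                            "sex": rng.integers(0, 2, 100).astype(float),
                            "icv": rng.normal(size=100)})
        model = sh.make_design(cov, "icv")
        Y = rng.normal(size=(100, 5))
        R = sh.residualize(Y, model)
        inner = model.design.T @ R / len(R)
        assert np.abs(inner).max() < 1e-8

    def test_collinear_design_rejected(self, rng):
        age = rng.normal(size=30)
        cov = pd.DataFrame({"age": age, "sex": 2.0 * age, "icv": rng.normal(size=30)})
        with pytest.raises(ValueError, match="rank-deficient"):
            sh.make_design(cov, "basic")

    def test_simulated_covariate_effects_removed(self):
        cfg = sh.SimulationConfig(n_subjects=2000, n_variants=200, n_vertices=10,
                                  seed=12, covariate_effects={"age": 0.3, "sex": 0.2})
        qc = sh.filter_variants(sh.generate_genotypes(cfg))
        y, gt = sh.simulate_vertex_phenotypes(qc, cfg)
        model = sh.make_design(gt.covariates, "basic")
        R = sh.residualize(y.values, model)
        age = gt.covariates["age"].to_numpy()
        cors = [abs(np.corrcoef(R[:, j], age)[0, 1]) for j in range(R.shape[1])]
        assert max(cors) < 0.01


class TestReML:
    def test_identity_grm_unidentified(self, rng):
        y = rng.normal(size=100)
        with pytest.warns(UserWarning, match="unidentified"):
            h2, se, p = sh.reml_h2(y, np.eye(100))
        assert h2 == 0.0 and p == 1.0

    def test_noiseless_genetic_phenotype_estimates_near_one(self, cohort):
        cfg, qc, grm = cohort
        X = qc.dosages
        p = X.mean(axis=0) / 2.0
        Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
        y = Z.sum(axis=1)  # pure standardized genotype sum, no noise
        h2, se, pval = sh.reml_h2(y, grm)
        assert h2 >= 0.95
        assert pval < 1e-6

    def test_eigendecomposition_cache_identical(self, cohort, rng):
        _, _, grm = cohort
        y = rng.normal(size=grm.n_subjects)
        direct = sh.reml_h2(y, grm)
        eig = _check_eig(grm)
        cached = sh.reml_h2(y, eig)
        assert direct == cached

    def test_zero_variance_phenotype_rejected(self, cohort):
        _, _, grm = cohort
        with pytest.raises(ValueError, match="variance"):
            sh.reml_h2(np.ones(grm.n_subjects), grm)

    def test_non_psd_grm_rejected(self, rng):
        K = np.eye(10)
        K[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive semi-definite"):
            sh.reml_h2(rng.normal(size=10), K)

    def test_many_columns_match_single_fits(self, cohort, rng):
        _, _, grm = cohort
        Y = rng.normal(size=(grm.n_subjects, 5))
        batch = reml_h2_many(Y, grm)
        for j in range(5):
            h2, se, p = sh.reml_h2(Y[:, j], grm)
            assert batch["h2"][j] == pytest.approx(h2, abs=5e-6)
            assert batch["p"][j] == pytest.approx(p, rel=1e-6)


class TestHasemanElston:
    def test_permuted_phenotype_estimates_zero(self, cohort, rng):
        cfg, qc, grm = cohort
        y, gt = sh.simulate_vertex_phenotypes(qc, cfg, h2_true=np.full(1, 0.5))
        est = sh.HasemanElston().fit(grm, rng.permutation(y.values[:, 0]))
        assert abs(est.h2_raw_) < 3.0 * est.se_

    def test_agrees_with_reml_on_simulated_vertices(self, cohort):
        cfg, qc, grm = cohort
        y, gt = sh.simulate_vertex_phenotypes(qc, cfg, h2_true=np.full(10, 0.4))
        res = reml_h2_many(y.values, grm)
        for j in range(10):
            he = sh.HasemanElston().fit(grm, y.values[:, j])
            joint_se = np.hypot(he.se_, np.nan_to_num(res["se"][j], nan=he.se_))
            assert abs(he.h2_raw_ - res["h2"][j]) < 2.0 * joint_se


class TestPermutation:
    def test_too_few_permutations_rejected(self, cohort, rng):
        _, _, grm = cohort
        with pytest.raises(ValueError, match="n_perm"):
            sh.permutation_p(rng.normal(size=grm.n_subjects), grm, n_perm=50)

    def test_p_never_zero_and_reproducible(self, cohort):
        cfg, qc, grm = cohort
        y, _ = sh.simulate_vertex_phenotypes(qc, cfg, h2_true=np.full(1, 0.8))
        p1 = sh.permutation_p(y.values[:, 0], grm, n_perm=120, seed=5)
        p2 = sh.permutation_p(y.values[:, 0], grm, n_perm=120, seed=5)
        assert p1 == p2
        assert 0.0 < p1 <= 1.0
        assert p1 >= 1.0 / 121.0


class TestH2Map:
    def test_subject_mismatch_listed(self, cohort, rng):
        _, _, grm = cohort
        n = grm.n_subjects
        mm = sh.ShapeMeasureMatrix(rng.normal(size=(n, 4)), measure="score",
                                   subject_ids=np.array([f"X{i}" for i in range(n)]))
        cov = pd.DataFrame({"age": rng.normal(size=n),
                            "sex": rng.integers(0, 2, n).astype(float)})
        with pytest.raises(ValueError, match="subjects"):
            sh.h2_map(mm, grm, sh.make_design(cov, "basic"))

    def test_map_fields_and_max_reported(self, cohort, rng):
        cfg, qc, grm = cohort
        h2 = np.zeros(15)
        h2[7] = 0.8
        y, gt = sh.simulate_vertex_phenotypes(qc, cfg, h2_true=h2)
        model = sh.make_design(gt.covariates, "basic")
        hmap = sh.h2_map(y.values, grm, model)
        assert hmap.n_vertices == 15
        assert ((hmap.h2 >= 0) & (hmap.h2 <= 1)).all()
        assert ((hmap.p > 0) & (hmap.p <= 1)).all()
        assert hmap.argmax_vertex == 7

    def test_map_tsv_round_trip_header(self, cohort, rng, tmp_path):
        _, _, grm = cohort
        hmap = sh.HeritabilityMap(np.array([0.1, 0.5]), np.array([0.1, 0.1]),
                                  np.array([0.5, 0.01]), np.array([False, True]),
                                  model="basic")
        path = tmp_path / "map.tsv"
        hmap.to_tsv(path)
        text = path.read_text()
        assert text.startswith("# model=basic")
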