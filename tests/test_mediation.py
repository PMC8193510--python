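"""Factor reduction and the mediation/moderation path models."""

import numpy as np
import pandas as pd
import pytest

from treescape.errors import TreescapeError
from treescape.mediation import (extract_factors, fit_mediation,
                                 fit_moderation, run_models)


def _unit_variance_chain(n, a, b, c_prime, rng):
    """x, m, y all unit variance in population, so the standardized paths
    equal the planted a, b, c' exactly in expectation."""
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(1 - a**2) * rng.standard_normal(n)
    res_var = 1 - (b**2 + c_prime**2 + 2 * a * b * c_prime)
    y = b * m + c_prime * x + np.sqrt(max(res_var, 1e-12)) * rng.standard_normal(n)
    return x, m, y


class TestExtractFactors:
    def test_composite_recovers_exact_latent(self, rng):
        latent = rng.standard_normal(100)
        df = pd.DataFrame({f"t{i}": 3 * latent + i for i in range(3)})
        fm = extract_factors(df, {"f": ["t0", "t1", "t2"]}, method="composite")
        assert abs(np.corrcoef(fm.scores["f"], latent)[0, 1]) == pytest.approx(1.0)
        assert fm.scores["f"].mean() == pytest.approx(0, abs=1e-12)
        assert np.std(fm.scores["f"].to_numpy()) == pytest.approx(1, rel=1e-9)

    def test_single_test_factor_is_standardized_test(self, rng):
        v = rng.standard_normal(50) * 4 + 2
        df = pd.DataFrame({"only": v})
        fm = extract_factors(df, {"f": ["only"]}, method="composite")
        assert np.allclose(fm.scores["f"], (v - v.mean()) / v.std())

    def test_efa_recovers_block_structure(self, rng):
        n, loading = 500, 0.8
        lat = rng.standard_normal((n, 3))
        cols = {}
        for j in range(3):
            for t in range(3):
                cols[f"v{j}{t}"] = loading * lat[:, j] + \
                    np.sqrt(1 - loading**2) * rng.standard_normal(n)
        df = pd.DataFrame(cols)
        fm = extract_factors(df, 3, method="efa")
        L = np.abs(fm.loadings.to_numpy())
        # each block of three tests should load dominantly on one factor
        for j in range(3):
            block = L[3 * j:3 * j + 3]
            dominant = block.max(axis=1)
            others = block.sum(axis=1) - dominant
            assert (dominant > 0.6).all()
            assert (others < 0.3 * 2).all()

    def test_listwise_deletion_warns(self, rng):
        df = pd.DataFrame({"a": [1.0, 2, np.nan, 4, 2], "b": [2.0, 1, 3, 4, 0],
                           "c": [1.0, 1, 2, 0, 3]})
        with pytest.warns(RuntimeWarning, match="deletion"):
            fm = extract_factors(df, {"f": ["a", "b", "c"]}, method="composite")
        assert len(fm.scores) == 4


class TestFitMediation:
    def test_noiseless_chain_exact(self, rng):
        x = rng.standard_normal(100)
        m = 0.5 * x
        y = 0.6 * m + 0.2 * x
        est = fit_mediation(x, m, y, n_boot=50, seed=0)[0]
        # standardized: m is perfectly correlated with x -> a = 1
        assert est.a == pytest.approx(1.0, abs=1e-10)
        # and c = c' + a*b must hold to machine precision
        assert est.c_total == pytest.approx(est.c_prime + est.indirect, abs=1e-10)

    def test_noiseless_unit_variance_chain_recovers_paths(self, rng):
        x, m, y = _unit_variance_chain(50000, 0.5, 0.6, 0.2, rng)
        est = fit_mediation(x, m, y, n_boot=50, seed=0)[0]
        assert est.a == pytest.approx(0.5, abs=0.02)
        assert est.b == pytest.approx(0.6, abs=0.02)
        assert est.c_prime == pytest.approx(0.2, abs=0.02)
        assert est.indirect == pytest.approx(0.30, abs=0.02)

    def test_total_effect_identity(self, rng):
        """c = c' + a*b exactly for OLS on standardized data, any noise."""
        x = rng.standard_normal(200)
        m = 0.4 * x + rng.standard_normal(200)
        y = 0.5 * m + 0.1 * x + rng.standard_normal(200)
        est = fit_mediation(x, m, y, n_boot=50, seed=0)[0]
        assert est.c_total == pytest.approx(est.c_prime + est.a * est.b, abs=1e-12)

    def test_ci_monotone_in_confidence_level(self, rng):
        x, m, y = _unit_variance_chain(300, 0.4, 0.5, 0.0, rng)
        est80 = fit_mediation(x, m, y, n_boot=400, seed=4, conf=0.80)[0]
        est95 = fit_mediation(x, m, y, n_boot=400, seed=4, conf=0.95)[0]
        assert est95.ci_low <= est80.ci_low
        assert est95.ci_high >= est80.ci_high

    def test_suppression_indirect_without_total(self, rng):
        """A significant indirect effect can coexist with a near-zero total
        effect when the direct path cancels it (suppression)."""
        x, m, y = _unit_variance_chain(800, 0.6, 0.5, -0.3, rng)
        est = fit_mediation(x, m, y, n_boot=800, seed=2)[0]
        assert est.significant  # indirect CI excludes 0
        assert abs(est.c_total) < abs(est.indirect)

    def test_collinear_covariates_raise(self, rng):
        x = rng.standard_normal(50)
        c = rng.standard_normal(50)
        with pytest.raises(TreescapeError, match="collinear"):
            fit_mediation(x, x + c, x - c, covariates=np.column_stack([c, 2 * c]),
                          n_boot=50, seed=0)

    def test_small_n_rejected(self, rng):
        with pytest.raises(TreescapeError):
            fit_mediation(rng.standard_normal(5), rng.standard_normal(5),
                          rng.standard_normal(5), n_boot=10, seed=0)


class TestFitModeration:
    def test_planted_interaction_detected(self, rng):
        n = 200
        g = np.array(["a"] * 100 + ["b"] * 100)
        x = rng.standard_normal(n)
        slope = np.where(g == "b", 1.0, 0.2)
        y = slope * x + 0.3 * rng.standard_normal(n)
        est = fit_moderation(x, g, y)
        assert est.p < 1e-6
        assert est.interaction_beta > 0

    def test_equal_slopes_calibrated(self, rng):
        ps = []
        for _ in range(60):
            x = rng.standard_normal(80)
            g = np.array(["a", "b"] * 40)
            y = 0.5 * x + rng.standard_normal(80)
            ps.append(fit_moderation(x, g, y).p)
        # under the null p should be roughly uniform: ~5% below .05
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.15

    def test_constant_group_raises(self, rng):
        with pytest.raises(TreescapeError, match="degenerate"):
            fit_moderation(rng.standard_normal(20), ["a"] * 20,
                           rng.standard_normal(20))


class TestRunModels:
    @pytest.fixture(scope="class")
    def cohort_tables(self):
        from treescape.pipeline import metrics_table
        from treescape.synthetic import (CohortSpec, generate_cohort,
                                         phenotype_table)
        spec = CohortSpec(n_subjects_per_group=25, n_nodes=60,
                          star_bias_age_slope=0.12, symptom_lf_slope=0.7,
                          noise_sd_topology=0.02, noise_sd_symptom=0.3,
                          mode="connectivity", seed=11)
        subs = generate_cohort(spec)
        pheno = phenotype_table(subs)
        mt = metrics_table([s.planted_tree for s in subs],
                           [s.subject_id for s in subs])
        return mt, pheno

    def test_model3_planted_chain_detected(self, cohort_tables):
        mt, pheno = cohort_tables
        rep = run_models(mt, pheno, 3, n_boot=600, seed=5)
        neg = [e for e in rep["estimates"] if e["outcome"] == "negative_symptom"][0]
        assert neg["ci"][0] > 0  # indirect CI excludes zero

    def test_model4_no_planted_interaction(self, cohort_tables):
        mt, pheno = cohort_tables
        rep = run_models(mt, pheno, 4, n_boot=100, seed=5)
        assert rep["p"] > 0.05

    def test_models_1_2_run_and_report(self, cohort_tables):
        mt, pheno = cohort_tables
        for mid in (1, 2):
            rep = run_models(mt, pheno, mid, n_boot=100, seed=5)
            assert {e["outcome"] for e in rep["estimates"]} == \
                {"working_memory", "executive_function"}

    def test_latent_structure_variant(self, cohort_tables):
        mt, pheno = cohort_tables
        rep = run_models(mt, pheno, 3, n_boot=200, seed=5,
                         use_latent_structure=True)
        assert rep["mediator"] == "latent_structure_pc1"
        neg = [e for e in rep["estimates"] if e["outcome"] == "negative_symptom"][0]
        assert np.isfinite(neg["indirect"])

    def test_invalid_model_id(self, cohort_tables):
        mt, pheno = cohort_tables
        with pytest.raises(ValueError):
            run_models(mt, pheno, 7)
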