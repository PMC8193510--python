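"""Synthetic cohort generator: planted topology, SPD covariance, mediation chain."""

import numpy as np
import pytest

from treescape.connectome import (ConnectivityMatrix, RoiTimeSeries,
                                  compute_connectivity, to_distance)
from treescape.errors import GenerationError, InvalidSizeError
from treescape.mediation import fit_mediation
from treescape.synthetic import (CohortSpec, generate_cohort,
                                 generate_tree_topology, phenotype_table,
                                 tree_to_covariance, write_cohort)
from treescape.trees import kruskal_mst, leaf_fraction
from treescape.similarity import overlap


class TestGenerateTreeTopology:
    def test_pure_star(self):
        t = generate_tree_topology(10, 1.0, 0)
        deg = sorted(t.degree_sequence())
        assert deg == [1] * 9 + [9]

    def test_pure_path(self):
        t = generate_tree_topology(10, 0.0, 0)
        assert leaf_fraction(t) == 0.2

    def test_leaf_fraction_monotone_in_bias(self, rng):
        means = []
        for bias in (0.2, 0.5, 0.8):
            lf = [leaf_fraction(generate_tree_topology(50, bias, rng))
                  for _ in range(200)]
            means.append(np.mean(lf))
        assert means[0] < means[1] < means[2]

    def test_valid_tree_invariants(self, rng):
        import networkx as nx
        for _ in range(10):
            t = generate_tree_topology(25, rng.uniform(0, 1), rng)
            g = t.to_networkx()
            assert nx.is_tree(g)
            assert len(t.edges) == 24

    def test_too_small_raises(self):
        with pytest.raises(InvalidSizeError):
            generate_tree_topology(3, 0.5, 0)


class TestTreeToCovariance:
    def test_spd_contract(self, rng):
        t = generate_tree_topology(30, 0.7, rng)
        sigma = tree_to_covariance(t, 0.6, 0.1)
        assert np.linalg.eigvalsh(sigma).min() > 0
        assert np.allclose(np.diag(sigma), 1.0)
        assert np.allclose(sigma, sigma.T)

    def test_tree_edges_dominate(self, rng):
        t = generate_tree_topology(20, 0.5, rng)
        sigma = tree_to_covariance(t, 0.6, 0.1)
        idx = {v: i for i, v in enumerate(t.nodes)}
        tree_mask = np.zeros_like(sigma, dtype=bool)
        for u, v in t.edges:
            tree_mask[idx[u], idx[v]] = tree_mask[idx[v], idx[u]] = True
        off = ~np.eye(len(sigma), dtype=bool)
        assert sigma[tree_mask].min() > sigma[off & ~tree_mask].max()

    def test_exact_mst_recovery_from_noise_free_covariance(self, rng):
        t = generate_tree_topology(40, 0.6, rng)
        sigma = tree_to_covariance(t, 0.6, 0.1)
        z = np.arctanh(np.clip(sigma, -0.999999, 0.999999))
        np.fill_diagonal(z, 0.0)
        c = ConnectivityMatrix("s", z, [str(v) for v in t.nodes])
        mst = kruskal_mst(to_distance(c))
        expected = frozenset(frozenset({str(u), str(v)}) for u, v in t.edges)
        assert mst.edge_set() == expected

    def test_pipeline_recovery_from_long_timeseries(self, rng):
        """Sampling T=5000 timepoints and running the full pipeline recovers
        the planted tree with overlap >= 0.9."""
        t = generate_tree_topology(30, 0.5, rng)
        sigma = tree_to_covariance(t, 0.6, 0.1)
        chol = np.linalg.cholesky(sigma)
        ts = RoiTimeSeries("s", chol @ rng.standard_normal((30, 5000)),
                           [str(v) for v in t.nodes])
        mst = kruskal_mst(to_distance(compute_connectivity(ts)))
        planted = kruskal_mst(to_distance(ConnectivityMatrix(
            "p", np.arctanh(np.clip(sigma, -0.99, 0.99)) * (1 - np.eye(30)),
            [str(v) for v in t.nodes])))
        assert overlap(mst, planted) >= 0.9

    def test_invalid_contrast_raises(self, rng):
        t = generate_tree_topology(10, 0.5, rng)
        with pytest.raises(GenerationError):
            tree_to_covariance(t, 0.3, 0.5)  # baseline >= edge_strength


class TestGenerateCohort:
    def test_determinism_byte_identical(self, tmp_path):
        spec = CohortSpec(n_subjects_per_group=4, n_nodes=20, n_timepoints=30, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(generate_cohort(spec), d1, spec)
        write_cohort(generate_cohort(spec), d2, spec)
        assert (d1 / "phenotypes.csv").read_bytes() == (d2 / "phenotypes.csv").read_bytes()
        assert (d1 / "truth.json").read_bytes() == (d2 / "truth.json").read_bytes()

    def test_age_leaf_fraction_correlation_positive(self):
        spec = CohortSpec(n_subjects_per_group=100, n_nodes=40,
                          star_bias_age_slope=0.3, noise_sd_topology=0.01,
                          star_bias_group_offset=0.0, mode="connectivity", seed=2)
        subs = generate_cohort(spec)
        ages = np.array([s.age for s in subs])
        lfs = np.array([leaf_fraction(s.planted_tree) for s in subs])
        assert np.corrcoef(ages, lfs)[0, 1] > 0.3

    def test_symptom_equation_recovered_at_zero_noise(self):
        """With zero symptom noise, b and c' are exact OLS solutions of the
        generative equation (patients carry the ratings)."""
        spec = CohortSpec(n_subjects_per_group=40, n_nodes=40,
                          symptom_lf_slope=0.5, symptom_direct_age_slope=0.2,
                          noise_sd_symptom=0.0, noise_sd_topology=0.05,
                          mode="connectivity", seed=3)
        subs = generate_cohort(spec)
        patients = [s for s in subs if s.group == "patient"]
        ages_all = np.array([s.age for s in subs])
        lfs_all = np.array([leaf_fraction(s.planted_tree) for s in subs])
        z_age = (ages_all - ages_all.mean()) / ages_all.std()
        z_lf = (lfs_all - lfs_all.mean()) / lfs_all.std()
        mask = np.array([s.group == "patient" for s in subs])
        y = np.array([s.behavior_scores["negative_symptom"] for s in patients])
        X = np.column_stack([np.ones(mask.sum()), z_lf[mask], z_age[mask]])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert beta[1] == pytest.approx(0.5, abs=1e-10)
        assert beta[2] == pytest.approx(0.2, abs=1e-10)

    def test_null_cohort_indirect_ci_covers_zero(self):
        """All planted slopes zero: the mediation CI should cover 0 in >= 90%
        of replicate cohorts."""
        covered = 0
        n_rep = 40
        for rep in range(n_rep):
            spec = CohortSpec(n_subjects_per_group=20, n_nodes=30,
                              star_bias_age_slope=0.0, symptom_lf_slope=0.0,
                              symptom_direct_age_slope=0.0,
                              star_bias_group_offset=0.0,
                              mode="connectivity", seed=1000 + rep)
            subs = generate_cohort(spec)
            pats = [s for s in subs if s.group == "patient"]
            age = np.array([s.age for s in pats])
            lf = np.array([leaf_fraction(s.planted_tree) for s in pats])
            y = np.array([s.behavior_scores["negative_symptom"] for s in pats])
            est = fit_mediation(age, lf, y, n_boot=300, seed=rep)[0]
            if est.ci_low <= 0 <= est.ci_high:
                covered += 1
        assert covered / n_rep >= 0.9

    def test_phenotype_schema(self):
        spec = CohortSpec(n_subjects_per_group=5, n_nodes=20, n_timepoints=30, seed=1)
        subs = generate_cohort(spec)
        ph = phenotype_table(subs)
        expected = {"subject_id", "group", "age", "gender", "motion", "medication",
                    "wms_digit_span", "wms_symbol_span", "wms_letter_number",
                    "dkefs_verbal_fluency", "cpt_dprime", "stroop_conflict",
                    "psychotic_symptom", "negative_symptom", "disorganization"}
        assert expected == set(ph.columns)
        assert ph[ph.group == "control"]["negative_symptom"].isna().all()
        assert ph["age"].between(*spec.age_range).all()
        # gender ratio mirrors the 29:11 default per group
        assert (ph[ph.group == "patient"]["gender"] == "M").sum() == round(5 * 29 / 40)

    def test_group_offset_raises_patient_leaf_fraction(self):
        spec = CohortSpec(n_subjects_per_group=30, n_nodes=40,
                          star_bias_group_offset=0.2, star_bias_age_slope=0.0,
                          mode="connectivity", seed=7)
        subs = generate_cohort(spec)
        lf_c = np.mean([leaf_fraction(s.planted_tree) for s in subs
                        if s.group == "control"])
        lf_p = np.mean([leaf_fraction(s.planted_tree) for s in subs
                        if s.group == "patient"])
        assert lf_p > lf_c
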