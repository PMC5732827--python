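"""Permutation tests, NBS, component summaries, distances, regression."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connectotopo import (component_summary, edge_distance_classify,
                          edge_t_matrix, metric_behavior_regression, nbs,
                          pearson_connectivity, permutation_test,
                          permutation_test_many)
from connectotopo.synthetic import SimulationConfig, simulate_timeseries
import oracles


class TestPermutationTest:
    def test_exhaustive_small_case_is_one_sixth(self):
        res = permutation_test([3, 4], [1, 2], alternative="greater",
                               exhaustive=True)
        assert res.p_value == pytest.approx(1 / 6)
        assert res.observed == 2.0

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.standard_normal(4)
            b = rng.standard_normal(5)
            res = permutation_test(a, b, alternative="greater", exhaustive=True)
            assert res.p_value == pytest.approx(
                oracles.exhaustive_perm_pvalue(a, b, "greater"))

    def test_identical_groups_not_significant(self, rng):
        vals = rng.standard_normal(12)
        res = permutation_test(vals, np.random.default_rng(1).permutation(vals),
                               n_perm=999, alternative="greater", seed=0)
        assert res.p_value > 0.4
        assert not res.reject

    def test_degenerate_constant_data_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            res = permutation_test([1.0, 1.0], [1.0, 1.0], n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_auto_direction_matches_observed_sign(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(2, 1, 10)
        res = permutation_test(a, b, n_perm=199, alternative="auto", seed=1)
        assert res.alternative == "less"
        assert res.observed < 0

    def test_pvalue_has_plus_one_correction(self, rng):
        a, b = rng.normal(5, 1, 8), rng.normal(0, 1, 8)
        res = permutation_test(a, b, n_perm=99, alternative="greater", seed=2)
        assert res.p_value >= 1 / 100  # can never be zero

    def test_vectorised_variant_matches_scalar_test(self, rng):
        """Column-wise results equal the scalar test run with the same
        seed (the permutation stream is shared)."""
        a = rng.normal(0, 1, (8, 3))
        b = rng.normal(0, 1, (10, 3))
        b[:, 2] -= 3.0  # one strong effect
        for col in range(3):
            out = permutation_test_many(a[:, [col]], b[:, [col]], n_perm=499,
                                        alternative="greater", seed=3)
            ref = permutation_test(a[:, col], b[:, col], n_perm=499,
                                   alternative="greater", seed=3)
            assert out.loc[0, "p_value"] == pytest.approx(ref.p_value)
            assert out.loc[0, "observed_diff"] == pytest.approx(ref.observed)
            assert out.loc[0, "critical_value"] == pytest.approx(ref.critical_value)
            assert bool(out.loc[0, "reject"]) == ref.reject
        full = permutation_test_many(a, b, n_perm=499, seed=3)
        assert full.loc[2, "p_value"] < 0.05 and full.loc[2, "reject"]


class TestEdgeT:
    def test_identical_groups_give_zero(self, rng):
        fc = np.stack([pearson_connectivity(rng.standard_normal((40, 6)))
                       for _ in range(4)])
        t = edge_t_matrix(fc, fc.copy())
        assert np.allclose(t, 0.0)

    def test_matches_scipy_per_edge(self, rng):
        fc_a = np.tanh(rng.normal(0, 0.3, (6, 5, 5)))
        fc_b = np.tanh(rng.normal(0.1, 0.3, (7, 5, 5)))
        for fc in (fc_a, fc_b):
            for s in fc:
                s[:] = (s + s.T) / 2
                np.fill_diagonal(s, 0.0)
        t = edge_t_matrix(fc_a, fc_b)
        za, zb = np.arctanh(fc_a), np.arctanh(fc_b)
        for i in range(5):
            for j in range(i + 1, 5):
                ref = stats.ttest_ind(za[:, i, j], zb[:, i, j]).statistic
                assert t[i, j] == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_edge_warns_and_zeroes(self):
        fc_a = np.zeros((3, 4, 4))
        fc_b = np.zeros((3, 4, 4))
        fc_a[:, 0, 1] = fc_a[:, 1, 0] = 0.5  # constant within both groups
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t = edge_t_matrix(fc_a, fc_b)
        assert t[0, 1] == 0.0


class TestNbs:
    def test_threshold_above_everything_gives_empty_result(self, rng):
        fc_a = np.tanh(rng.normal(0, 0.2, (5, 6, 6)))
        fc_b = np.tanh(rng.normal(0, 0.2, (5, 6, 6)))
        res = nbs(fc_a, fc_b, threshold=50.0, n_perm=49, seed=0)
        assert res.components == []

    def test_masked_nbs_recovers_lesion_given_its_nodes(self, small_gt):
        """With the analysis restricted to the lesioned regions, the
        weakened subnetwork surfaces as a significant component."""
        cfg = SimulationConfig(n_patients=10, n_controls=12, n_timepoints=229,
                               seed=17)
        ts = simulate_timeseries(small_gt, cfg)
        pat = np.stack([pearson_connectivity(s) for s in ts.subjects
                        if s.group == "patient"])
        ctl = np.stack([pearson_connectivity(s) for s in ts.subjects
                        if s.group == "control"])
        lesion_nodes = sorted({v for e in small_gt.affected_edges for v in e})
        res = nbs(pat, ctl, threshold=2.441, n_perm=199, seed=5,
                  node_mask=lesion_nodes)
        truth = {tuple(sorted(e)) for e in small_gt.affected_edges}
        found = {e for c in res.significant for e in c.edges}
        assert len(found & truth) / len(truth) >= 0.9

    def test_component_pvalues_use_plus_one_correction(self, rng):
        fc_a = np.tanh(rng.normal(0, 0.2, (6, 8, 8)))
        fc_b = np.tanh(rng.normal(0, 0.2, (6, 8, 8)))
        res = nbs(fc_a, fc_b, threshold=1.5, n_perm=49, seed=1)
        for c in res.components:
            assert 1 / 50 <= c.p_value <= 1.0


class TestComponentSummary:
    def test_empty_and_disjoint_edges(self):
        assert component_summary([]) == (0, 0, 0)
        assert component_summary([(1, 2), (3, 4)]) == (4, 2, 2)

    def test_duplicates_collapsed_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            out = component_summary([(1, 2), (2, 1), (2, 3)])
        assert out == (3, 2, 1)

    def test_matches_unionfind_oracle_on_random_lists(self, rng):
        for _ in range(20):
            edges = [tuple(sorted(rng.integers(0, 15, 2).tolist()))
                     for _ in range(12)]
            edges = [e for e in set(edges) if e[0] != e[1]]
            nodes, n_edges, n_comp = component_summary(edges)
            comps = oracles.connected_edge_components(edges)
            assert n_comp == len(comps)
            assert nodes == sum(len(c) for c in comps)
            assert n_edges == len(edges)


class TestDistanceClassification:
    @staticmethod
    def centroids(rows):
        return pd.DataFrame(rows, columns=["region_id", "name", "x", "y", "z"])

    def test_3_4_5_triangle(self):
        cents = self.centroids([(1, "a", 0, 0, 0), (2, "b", 3, 4, 0)])
        out = edge_distance_classify([(1, 2)], cents, cutoff_mm=75.0)
        assert out[0].distance_mm == pytest.approx(5.0)
        assert not out[0].long_range

    def test_exact_cutoff_counts_as_short(self):
        cents = self.centroids([(1, "a", 0, 0, 0), (2, "b", 75.0, 0, 0)])
        out = edge_distance_classify([(1, 2)], cents)
        assert not out[0].long_range
        cents2 = self.centroids([(1, "a", 0, 0, 0), (2, "b", 75.0001, 0, 0)])
        assert edge_distance_classify([(1, 2)], cents2)[0].long_range

    def test_missing_region_named_in_error(self):
        cents = self.centroids([(1, "a", 0, 0, 0)])
        with pytest.raises(KeyError, match="region 2"):
            edge_distance_classify([(1, 2)], cents)

    def test_rigid_translation_invariance(self, rng):
        rows = [(i, f"r{i}", *rng.uniform(-70, 70, 3)) for i in range(1, 6)]
        cents = self.centroids(rows)
        shift = rng.uniform(-50, 50, 3)
        shifted = cents.copy()
        shifted[["x", "y", "z"]] += shift
        edges = [(1, 2), (2, 5), (3, 4)]
        d0 = [f.distance_mm for f in edge_distance_classify(edges, cents)]
        d1 = [f.distance_mm for f in edge_distance_classify(edges, shifted)]
        assert np.allclose(d0, d1)


class TestRegression:
    def test_exact_linear_relation(self, rng):
        metric = rng.standard_normal(30)
        tab = pd.DataFrame({"m": metric, "score": 2.0 * metric})
        res = metric_behavior_regression(tab, "m", "score", confounders=())
        assert res.metric_coefficient == pytest.approx(2.0)
        assert res.adjusted_r_squared == pytest.approx(1.0)

    def test_independent_score_has_no_fit(self, rng):
        n = 500
        tab = pd.DataFrame({
            "m": rng.standard_normal(n), "age": rng.normal(67, 5, n),
            "sex": rng.integers(0, 2, n), "education": rng.normal(12, 4, n),
            "score": rng.standard_normal(n)})
        res = metric_behavior_regression(tab, "m", "score")
        assert abs(res.adjusted_r_squared) < 0.05

    def test_matches_normal_equations_oracle(self, rng):
        n = 25
        tab = pd.DataFrame({
            "m": rng.standard_normal(n), "age": rng.normal(67, 5, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(12, 4, n),
            "score": rng.standard_normal(n)})
        res = metric_behavior_regression(tab, "m", "score")
        x = np.column_stack([np.ones(n), tab[["m", "age", "sex", "education"]]])
        y = tab["score"].to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        adj = 1 - (1 - r2) * (n - 1) / (n - 4 - 1)
        assert res.metric_coefficient == pytest.approx(beta[1], abs=1e-10)
        assert res.adjusted_r_squared == pytest.approx(adj, abs=1e-10)

    def test_collinear_design_rejected(self, rng):
        n = 20
        age = rng.normal(67, 5, n)
        tab = pd.DataFrame({"m": age * 2, "age": age, "sex": rng.integers(0, 2, n),
                            "education": rng.normal(12, 4, n),
                            "score": rng.standard_normal(n)})
        with pytest.raises(ValueError, match="rank deficient"):
            metric_behavior_regression(tab, "m", "score")

    def test_small_residual_df_warns(self, rng):
        n = 10
        tab = pd.DataFrame({
            "m": rng.standard_normal(n), "age": rng.normal(67, 5, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(12, 4, n),
            "score": rng.standard_normal(n)})
        with pytest.warns(UserWarning, match="df"):
            metric_behavior_regression(tab, "m", "score")
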