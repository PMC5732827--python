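"""Graph metrics against closed forms and brute-force oracles."""
import numpy as np
import pytest

from connectotopo import (RandomEnsembleSpec, auc, characteristic_path_length,
                          clustering_coefficient, degree_preserving_randomize,
                          global_efficiency, local_efficiency, nodal_metrics,
                          normalized_smallworld, shortest_path_lengths,
                          threshold_by_sparsity)
from conftest import random_graph
import oracles


def complete(n):
    a = np.ones((n, n)) - np.eye(n)
    return a


def path3():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1.0
    return a


def star(leaves):
    n = leaves + 1
    a = np.zeros((n, n))
    a[0, 1:] = a[1:, 0] = 1.0
    return a


class TestClosedForms:
    def test_complete_graph_metrics(self):
        a = complete(5)
        per_node, cp = clustering_coefficient(a)
        assert np.allclose(per_node, 1.0) and cp == 1.0
        lp, unreach = characteristic_path_length(complete(4))
        assert lp == 1.0 and unreach == 0.0
        assert global_efficiency(a) == 1.0
        assert local_efficiency(a) == 1.0

    def test_star_clustering_and_betweenness(self):
        a = star(3)
        per_node, cp = clustering_coefficient(a)
        assert np.all(per_node == 0.0) and cp == 0.0
        nod = nodal_metrics(a)
        assert nod["betweenness"][0] == 1.0
        assert np.all(nod["betweenness"][1:] == 0.0)

    def test_path_graph_values(self):
        a = path3()
        d = shortest_path_lengths(a)
        assert d[0, 2] == 2.0
        lp, _ = characteristic_path_length(a)
        assert lp == pytest.approx(4.0 / 3.0)
        assert global_efficiency(a) == pytest.approx(5.0 / 6.0)
        assert nodal_metrics(a)["betweenness"][1] == 1.0

    def test_disconnected_distances_are_infinite(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1.0
        d = shortest_path_lengths(a)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
        lp, unreach = characteristic_path_length(a)
        assert lp == 1.0 and unreach == pytest.approx(4.0 / 6.0)

    def test_harmonic_convention_matches_inverse_efficiency(self):
        a = path3()
        lp, _ = characteristic_path_length(a, convention="harmonic")
        assert lp == pytest.approx(1.0 / global_efficiency(a))


class TestOracleEquivalence:
    """Spot-check equivalence on a randomized suite (the full 500-graph
    sweep runs in the acceptance tests)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_all_metrics_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a = random_graph(rng)
            d_o = oracles.floyd_warshall(a)
            assert np.array_equal(shortest_path_lengths(a), d_o)
            per_node, _ = clustering_coefficient(a)
            assert np.allclose(per_node, oracles.clustering_by_triangle_enumeration(a))
            assert global_efficiency(a) == pytest.approx(
                oracles.global_efficiency_pairsum(d_o), abs=1e-12)
            assert local_efficiency(a) == pytest.approx(
                oracles.local_efficiency_bruteforce(a), abs=1e-12)
            nod = nodal_metrics(a)
            assert np.allclose(nod["degree"], a.sum(axis=1))
            assert np.allclose(nod["nodal_efficiency"],
                               oracles.nodal_efficiency_pairsum(d_o), atol=1e-12)
            assert np.allclose(nod["betweenness"],
                               oracles.betweenness_by_path_counts(a), atol=1e-10)


class TestRandomization:
    def test_degree_sequence_preserved_and_seeded(self, rng):
        a = random_graph(rng, n_max=20, p=0.3)
        spec = RandomEnsembleSpec(n_random=5, seed=42)
        ens = degree_preserving_randomize(a, spec)
        for r in ens:
            assert np.array_equal(np.sort(r.sum(axis=1)), np.sort(a.sum(axis=1)))
        ens2 = degree_preserving_randomize(a, spec)
        assert all(np.array_equal(x, y) for x, y in zip(ens, ens2))

    def test_rewiring_lowers_lattice_clustering(self):
        import networkx as nx
        a = nx.to_numpy_array(nx.watts_strogatz_graph(20, 4, 0.0))
        _, cp_lattice = clustering_coefficient(a)
        ens = degree_preserving_randomize(a, RandomEnsembleSpec(n_random=10, seed=1))
        cp_rand = np.mean([clustering_coefficient(r)[1] for r in ens])
        assert cp_rand < cp_lattice

    def test_star_swap_quota_warns(self):
        with pytest.warns(UserWarning, match="swap quota"):
            degree_preserving_randomize(star(5), RandomEnsembleSpec(n_random=1, seed=0))

    def test_self_normalization_is_unity(self):
        a = complete(4)
        gamma, lam, sigma = normalized_smallworld(a, [a])
        assert gamma == lam == sigma == 1.0

    def test_zero_clustering_ensemble_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalized_smallworld(path3(), [path3()])

    def test_watts_strogatz_is_smallworld(self):
        import networkx as nx
        a = nx.to_numpy_array(nx.watts_strogatz_graph(90, 8, 0.1, seed=2))
        ens = degree_preserving_randomize(a, RandomEnsembleSpec(n_random=10, seed=3))
        gamma, lam, sigma = normalized_smallworld(a, ens)
        assert gamma > 1.0
        # at this rewiring probability lambda sits just above 1.2
        assert lam < 1.3
        assert sigma > 1.5
        assert sigma == gamma / lam  # stored ratio is exact


class TestAuc:
    GRID = np.round(np.linspace(0.10, 0.34, 25), 2)

    def test_constant_curve_is_rectangle(self):
        assert auc(np.full(25, 3.0), self.GRID) == pytest.approx(0.24 * 3.0)

    def test_linear_ramp_is_triangle(self):
        assert auc(np.linspace(0, 1, 25), self.GRID) == pytest.approx(0.12)

    def test_random_curve_matches_manual_trapezoid(self, rng):
        y = rng.standard_normal(25)
        manual = sum((y[i] + y[i + 1]) / 2 * (self.GRID[i + 1] - self.GRID[i])
                     for i in range(24))
        assert auc(y, self.GRID) == pytest.approx(manual, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            auc(np.zeros(10), self.GRID)


class TestSweepMonotonicity:
    def test_efficiency_nondecreasing_on_nested_graphs(self, rng):
        c = rng.standard_normal((20, 20))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 0.0)
        effs = [global_efficiency(threshold_by_sparsity(c, s))
                for s in (0.2, 0.4, 0.6, 0.8)]
        assert all(b >= a for a, b in zip(effs, effs[1:]))
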