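"""Synthetic generator: substrate, lesion, signals, covariates."""
import numpy as np
import pytest

from connectotopo import (CovariateModel, SimulationConfig, make_ground_truth,
                          pearson_connectivity, simulate_covariates,
                          simulate_timeseries)
from connectotopo.synthetic import (group_covariance, link_beta_for_r2,
                                    nearest_correlation)
import oracles


class TestGroundTruth:
    def test_unrewired_lattice_is_regular(self):
        gt = make_ground_truth(n_nodes=90, k=8, p=0.0, n_affected_edges=0, seed=0)
        assert np.all(gt.adjacency.sum(axis=1) == 8)

    def test_four_cycle_closed_form(self):
        gt = make_ground_truth(n_nodes=4, k=2, p=0.0, n_affected_edges=0, seed=0)
        expected = np.array([[0, 1, 0, 1],
                             [1, 0, 1, 0],
                             [0, 1, 0, 1],
                             [1, 0, 1, 0]], dtype=float)
        assert np.array_equal(gt.adjacency, expected)

    def test_affected_edges_connected_via_unionfind_oracle(self):
        gt = make_ground_truth(n_nodes=90, k=8, p=0.1, n_affected_edges=13, seed=7)
        assert len(gt.affected_edges) == 13
        comps = oracles.connected_edge_components(gt.affected_edges)
        assert len(comps) == 1
        for i, j in gt.affected_edges:  # lesion is a subset of the substrate
            assert gt.adjacency[i, j] == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="k must be even"):
            make_ground_truth(n_nodes=10, k=3)
        with pytest.raises(ValueError, match="n_nodes"):
            make_ground_truth(n_nodes=3, k=2)
        with pytest.raises(ValueError, match="affected"):
            make_ground_truth(n_nodes=10, k=2, n_affected_edges=99)


class TestCovariance:
    def test_nearest_correlation_is_valid(self, rng):
        m = rng.standard_normal((20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        fixed = nearest_correlation(m)
        assert np.allclose(np.diag(fixed), 1.0)
        assert np.linalg.eigvalsh(fixed).min() > 0

    def test_lesion_realised_in_covariance(self, small_gt):
        sc = group_covariance(small_gt, 0.3, "control")
        sp = group_covariance(small_gt, 0.3, "patient")
        for i, j in small_gt.affected_edges:
            assert sp[i, j] < sc[i, j] - 0.5 * small_gt.effect_size


class TestSignals:
    def test_same_seed_is_byte_identical(self, small_gt):
        cfg = SimulationConfig(n_patients=2, n_controls=2, n_timepoints=60, seed=9)
        a = simulate_timeseries(small_gt, cfg)
        b = simulate_timeseries(small_gt, cfg)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.data, sb.data)
            assert sa.covariates == sb.covariates

    def test_null_effect_gives_no_group_difference(self):
        """Monte-Carlo: with effect 0 the pooled edge-wise correlation
        difference is zero within 3 standard errors over 50 replicates."""
        gt = make_ground_truth(n_nodes=30, k=4, p=0.1, n_affected_edges=6,
                               effect_size=0.0, seed=2)
        rng = np.random.default_rng(12)
        diffs = []
        iu = np.triu_indices(30, 1)
        for _ in range(50):
            cfg = SimulationConfig(n_patients=4, n_controls=4, n_timepoints=120,
                                   seed=int(rng.integers(2**31)))
            ts = simulate_timeseries(gt, cfg)
            cs = {g: [] for g in ("patient", "control")}
            for s in ts.subjects:
                cs[s.group].append(pearson_connectivity(s)[iu])
            diffs.append(np.mean(cs["patient"]) - np.mean(cs["control"]))
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se

    def test_positive_effect_lowers_affected_edges(self, small_gt):
        rng = np.random.default_rng(5)
        per_edge = []
        for _ in range(10):
            cfg = SimulationConfig(n_patients=4, n_controls=4, n_timepoints=150,
                                   seed=int(rng.integers(2**31)))
            ts = simulate_timeseries(small_gt, cfg)
            cs = {g: [] for g in ("patient", "control")}
            for s in ts.subjects:
                cs[s.group].append(pearson_connectivity(s))
            d = np.mean(cs["patient"], axis=0) - np.mean(cs["control"], axis=0)
            per_edge.append([d[i, j] for i, j in small_gt.affected_edges])
        mean_per_edge = np.mean(per_edge, axis=0)
        assert np.all(mean_per_edge < 0)

    def test_band_must_sit_inside_nyquist(self):
        with pytest.raises(ValueError, match="band"):
            SimulationConfig(band=(0.01, 0.4), tr_seconds=2.0)


class TestCovariates:
    def test_fixed_seed_reproduces_table(self):
        cfg = SimulationConfig(seed=4)
        a = simulate_covariates(cfg, seed=99)
        b = simulate_covariates(cfg, seed=99)
        assert a.equals(b)
        assert list(a["group"]).count("patient") == 12
        assert set(a.columns) >= {"subject_id", "group", "age", "sex",
                                  "education", "mmse"}

    def test_linked_mmse_recovers_target_r2(self):
        """beta chosen for population R^2 = 0.6 yields matching fits."""
        rng = np.random.default_rng(8)
        metric_sd, noise_sd = 2.0, 1.5
        beta = link_beta_for_r2(0.6, metric_sd, noise_sd)
        # centre MMSE mid-scale so the [0, 30] clip never binds
        model = CovariateModel(mmse_mean=15.0, link_beta=beta,
                               link_noise_sd=noise_sd)
        r2s = []
        for _ in range(40):
            cfg = SimulationConfig(n_patients=60, n_controls=60,
                                   covariate_model=model,
                                   seed=int(rng.integers(2**31)))
            metric = rng.normal(0.0, metric_sd, 120)
            tab = simulate_covariates(cfg, metric_values=metric,
                                      seed=int(rng.integers(2**31)))
            x = np.column_stack([np.ones(120), metric])
            y = tab["mmse"].to_numpy()
            beta_hat, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta_hat
            r2 = 1 - resid.var() / y.var()
            r2s.append(1 - (1 - r2) * 119 / 118)
        assert np.mean(r2s) == pytest.approx(0.6, abs=0.05)

    def test_null_link_gives_no_association(self):
        cfg = SimulationConfig(n_patients=100, n_controls=100, seed=21)
        metric = np.random.default_rng(3).normal(size=200)
        tab = simulate_covariates(cfg, metric_values=metric, seed=77)
        r = np.corrcoef(metric, tab["mmse"])[0, 1]
        assert abs(r) < 0.2
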