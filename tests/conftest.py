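import numpy as np
import pytest

from connectotopo import (GroundTruthNetwork, RoiTimeSeriesSet,
                          SimulationConfig, Subject, make_ground_truth,
                          simulate_timeseries)


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture(scope="session")
def small_gt():
    """30-node substrate with a 6-edge connected lesion."""
    return make_ground_truth(n_nodes=30, k=4, p=0.1, n_affected_edges=6,
                             effect_size=0.3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_gt):
    """Quick two-group dataset: 5 patients / 6 controls, 120 time points."""
    cfg = SimulationConfig(n_patients=5, n_controls=6, n_timepoints=120, seed=3)
    return simulate_timeseries(small_gt, cfg)


@pytest.fixture
def tiny_set():
    """Hand-built 3-subject dataset for I/O and preprocessing tests."""
    rng = np.random.default_rng(0)
    subjects = [
        Subject(subject_id=f"{i:03d}", data=rng.standard_normal((40, 5)),
                group="patient" if i == 1 else "control",
                covariates={"age": 60.0 + i, "sex": i % 2, "education": 12.0,
                            "mmse": 28.0})
        for i in range(1, 4)
    ]
    return RoiTimeSeriesSet(subjects, tr_seconds=2.0)


def random_graph(rng, n_max=12, p=None):
    """Random simple undirected graph adjacency for oracle suites."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.2, 0.8)) if p is None else p
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, k=1)
    return a + a.T
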