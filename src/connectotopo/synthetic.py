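"""Synthetic two-group ROI time-series generator with known ground truth.

Emulates the study design the pipeline targets: 12 patients vs 24
controls, a 90-region parcellation, band-limited (0.01-0.08 Hz, TR 2 s)
signals whose pairwise correlations reflect a small-world substrate, and a
connected subnetwork of edges whose coupling is weakened in the patient
group. Everything downstream — thresholding, metrics, permutation tests,
the network-based statistic — can therefore be validated against known
structure without any acquired data.

Signal model
------------
Signals are multivariate Gaussian with a network-structured covariance:
the substrate adjacency ``A`` (Watts-Strogatz ring lattice with rewiring)
is scaled to a target edge correlation ``edge_corr`` (default 0.3), the
diagonal set to 1, and the matrix repaired to the nearest valid
correlation matrix by eigenvalue clipping. In the patient group the
entries of a chosen connected edge set are reduced by ``effect_size``
before repair. Samples are then zero-phase band-pass filtered, which
leaves the cross-correlation structure intact (the same filter is applied
to every channel) while giving the signals realistic autocorrelation.
Only second-order structure matters downstream, so no hemodynamic model
is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .dataset import RoiTimeSeriesSet, Subject
from .preprocess import bandpass_array

__all__ = [
    "GroundTruthNetwork",
    "SimulationConfig",
    "CovariateModel",
    "make_ground_truth",
    "group_covariance",
    "simulate_timeseries",
    "simulate_covariates",
    "nearest_correlation",
]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A known connectivity substrate plus the patient-group lesion.

    ``affected_edges`` always form a single connected component of the
    substrate (mirroring the kind of spatially coherent disruption the
    network-based statistic is designed to detect).
    """

    n_nodes: int
    adjacency: np.ndarray
    k: int
    p: float
    affected_edges: tuple
    effect_size: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape does not match n_nodes")
        if not np.array_equal(a, a.T) or np.diag(a).any():
            raise ValueError("adjacency must be symmetric with zero diagonal")
        for i, j in self.affected_edges:
            if not a[i, j]:
                raise ValueError(f"affected edge ({i}, {j}) not present in substrate")

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class CovariateModel:
    """Distributions for the participants table.

    Calibrated loosely to an elderly T2DM cohort: age ~ N(67, 5) years,
    education ~ N(12, 5) years, a 1:2 male:female ratio, MMSE around 28.
    When ``link_beta`` is nonzero and a metric value is supplied per
    subject, MMSE = intercept + beta * metric + confounder terms + noise,
    giving the regression stage a recoverable ground-truth association.
    """

    age_mean: float = 67.0
    age_sd: float = 5.0
    male_fraction: float = 1.0 / 3.0
    education_mean: float = 12.0
    education_sd: float = 5.0
    mmse_mean: float = 28.0
    mmse_sd: float = 2.0
    link_beta: float = 0.0
    link_noise_sd: float = 1.0
    link_age_beta: float = 0.0
    link_education_beta: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the emulated acquisition: 12 patients, 24 controls,
    229 retained volumes (239 acquired minus 10 discarded) at TR = 2 s,
    pass-band 0.01-0.08 Hz.
    """

    n_patients: int = 12
    n_controls: int = 24
    n_timepoints: int = 229
    tr_seconds: float = 2.0
    band: tuple = (0.01, 0.08)
    edge_corr: float = 0.3
    noise_sd: float = 0.0
    seed: int | None = None
    covariate_model: CovariateModel = field(default_factory=CovariateModel)

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("both groups must be non-empty")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be at least 3")
        nyq = 1.0 / (2.0 * self.tr_seconds)
        low, high = self.band
        if not (0.0 < low < high < nyq):
            raise ValueError(
                f"band {self.band} must lie strictly inside (0, {nyq}) Hz"
            )


def make_ground_truth(
    n_nodes: int = 90,
    k: int = 8,
    p: float = 0.1,
    n_affected_edges: int = 13,
    effect_size: float = 0.2,
    seed: int | None = None,
    max_retries: int = 100,
) -> GroundTruthNetwork:
    """Draw a connected small-world substrate and a connected lesion.

    The substrate is a Watts-Strogatz graph (ring neighbourhood ``k``,
    rewiring probability ``p``), redrawn until connected; simulated
    control networks built on it show the small-world signature
    (normalised clustering > 1 at near-unit normalised path length).
    ``affected_edges`` are grown edge-by-edge from a random seed edge so
    that they induce exactly one connected component.
    """
    if n_nodes < 4:
        raise ValueError(f"n_nodes must be >= 4, got {n_nodes}")
    if k % 2 or not (2 <= k < n_nodes):
        raise ValueError(f"k must be even with 2 <= k < n_nodes, got {k}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"rewiring probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)

    g = None
    for _ in range(max_retries):
        cand = nx.watts_strogatz_graph(n_nodes, k, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(cand):
            g = cand
            break
    if g is None:
        raise RuntimeError(
            f"could not draw a connected substrate in {max_retries} tries "
            f"(n_nodes={n_nodes}, k={k}, p={p})"
        )

    edges = sorted(tuple(sorted(e)) for e in g.edges)
    if n_affected_edges > len(edges):
        raise ValueError(
            f"requested {n_affected_edges} affected edges but the substrate "
            f"has only {len(edges)}"
        )
    # Grow a *dense* connected edge set: whenever an unchosen substrate edge
    # has both endpoints already covered, prefer it over expanding to a new
    # node. This emulates a compact lesion (e.g. 13 connections among ~9
    # regions) rather than a sprawling tree, so the affected nodes each lose
    # several connections.
    affected: list = []
    if n_affected_edges > 0:
        chosen = set()
        nodes_in = set()
        first = edges[rng.integers(len(edges))]
        chosen.add(first)
        nodes_in.update(first)
        while len(chosen) < n_affected_edges:
            internal = [
                e for e in edges
                if e not in chosen and e[0] in nodes_in and e[1] in nodes_in
            ]
            frontier = internal or [
                e for e in edges
                if e not in chosen and (e[0] in nodes_in or e[1] in nodes_in)
            ]
            if not frontier:  # unreachable: substrate is connected
                raise RuntimeError("could not grow a connected affected edge set")
            nxt = frontier[rng.integers(len(frontier))]
            chosen.add(nxt)
            nodes_in.update(nxt)
        affected = sorted(chosen)

    adjacency = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=float)
    return GroundTruthNetwork(
        n_nodes=n_nodes,
        adjacency=adjacency,
        k=k,
        p=p,
        affected_edges=tuple(affected),
        effect_size=effect_size,
    )


def nearest_correlation(
    sigma: np.ndarray,
    min_eig: float = 1e-6,
    max_jitter_rounds: int = 10,
) -> np.ndarray:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``min_eig``, the matrix reconstructed and
    rescaled to unit diagonal; if a Cholesky factorisation still fails,
    diagonal jitter is added in growing steps. Failing after
    ``max_jitter_rounds`` raises.
    """
    s = 0.5 * (sigma + sigma.T)
    w, v = np.linalg.eigh(s)
    s = (v * np.clip(w, min_eig, None)) @ v.T
    d = np.sqrt(np.diag(s))
    s = s / np.outer(d, d)
    jitter = min_eig
    for _ in range(max_jitter_rounds):
        try:
            np.linalg.cholesky(s)
            return s
        except np.linalg.LinAlgError:
            s = s + jitter * np.eye(len(s))
            d = np.sqrt(np.diag(s))
            s = s / np.outer(d, d)
            jitter *= 10.0
    raise np.linalg.LinAlgError("covariance not positive definite after repair")


def group_covariance(gt: GroundTruthNetwork, edge_corr: float, group: str) -> np.ndarray:
    """Correlation matrix implied by the substrate for one group.

    Controls: identity plus ``edge_corr`` on substrate edges. Patients:
    the same with ``effect_size`` subtracted on each affected edge. Both
    are repaired to valid correlation matrices.
    """
    sigma = np.eye(gt.n_nodes) + edge_corr * gt.adjacency
    if group == "patient":
        for i, j in gt.affected_edges:
            sigma[i, j] -= gt.effect_size
            sigma[j, i] -= gt.effect_size
    elif group != "control":
        raise ValueError(f"unknown group {group!r}")
    return nearest_correlation(sigma)


def simulate_timeseries(gt: GroundTruthNetwork, cfg: SimulationConfig) -> RoiTimeSeriesSet:
    """Sample band-limited signals for every subject of both groups.

    Identical ``cfg.seed`` yields a byte-identical dataset. Covariates are
    attached from :func:`simulate_covariates` using the same seed stream.
    """
    rng = np.random.default_rng(cfg.seed)
    chol = {
        grp: np.linalg.cholesky(group_covariance(gt, cfg.edge_corr, grp))
        for grp in ("patient", "control")
    }
    low, high = cfg.band
    fs = 1.0 / cfg.tr_seconds

    labels = ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls
    subjects = []
    for idx, grp in enumerate(labels, start=1):
        z = rng.standard_normal((cfg.n_timepoints, gt.n_nodes))
        x = z @ chol[grp].T
        if cfg.noise_sd > 0:
            x = x + cfg.noise_sd * rng.standard_normal(x.shape)
        x = bandpass_array(x, low, high, fs)
        subjects.append(Subject(subject_id=f"{idx:03d}", data=x, group=grp))

    ts = RoiTimeSeriesSet(subjects, tr_seconds=cfg.tr_seconds)
    table = simulate_covariates(cfg, seed=rng.integers(2**31))
    for s, (_, row) in zip(ts.subjects, table.iterrows()):
        s.covariates = {
            c: row[c] for c in table.columns if c not in ("subject_id", "group")
        }
    return ts


def link_beta_for_r2(r2: float, metric_sd: float, noise_sd: float) -> float:
    """Slope giving a target population R-squared for the MMSE link.

    For MMSE = beta * metric + noise, R^2 = b^2 v / (b^2 v + s^2) with
    v = metric variance and s^2 = noise variance; invert for beta.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if r2 == 0.0:
        return 0.0
    return noise_sd / metric_sd * np.sqrt(r2 / (1.0 - r2))


def simulate_covariates(
    cfg: SimulationConfig,
    metric_values: np.ndarray | None = None,
    seed: int | None = None,
) -> "pd.DataFrame":
    """Draw the participants table (id, group, age, sex, education, MMSE, AVLT).

    When ``metric_values`` (one per subject, patients first) is given and
    the covariate model carries a nonzero ``link_beta``, MMSE is generated
    as a linear function of the metric plus confounder terms and noise;
    the generating coefficients are recorded in ``DataFrame.attrs["link"]``.
    """
    import pandas as pd

    m = cfg.covariate_model
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_patients + cfg.n_controls
    groups = ["patient"] * cfg.n_patients + ["control"] * cfg.n_controls

    age = np.clip(rng.normal(m.age_mean, m.age_sd, n), 55, 85)
    sex = (rng.random(n) >= m.male_fraction).astype(int)  # 0 = male, 1 = female
    education = np.clip(rng.normal(m.education_mean, m.education_sd, n), 0, 22)

    if metric_values is not None and m.link_beta != 0.0:
        metric_values = np.asarray(metric_values, dtype=float)
        if metric_values.shape != (n,):
            raise ValueError(f"metric_values must have length {n}")
        mmse = (
            m.mmse_mean
            + m.link_beta * (metric_values - metric_values.mean())
            + m.link_age_beta * (age - m.age_mean)
            + m.link_education_beta * (education - m.education_mean)
            + rng.normal(0.0, m.link_noise_sd, n)
        )
    else:
        mmse = rng.normal(m.mmse_mean, m.mmse_sd, n)
    mmse = np.clip(mmse, 0, 30)

    # AVLT immediate recalls climb across trials; delayed and recognition follow
    avlt_means = {"avlt_ir1": 6.9, "avlt_ir2": 9.8, "avlt_ir3": 11.0,
                  "avlt_delayed": 10.2, "avlt_recognition": 12.4}
    avlt = {k: np.clip(rng.normal(mu, 2.2, n), 0, 15) for k, mu in avlt_means.items()}

    table = pd.DataFrame({
        "subject_id": [f"{i:03d}" for i in range(1, n + 1)],
        "group": groups,
        "age": np.round(age, 1),
        "sex": sex,
        "education": np.round(education, 1),
        "mmse": np.round(mmse, 1),
        **{k: np.round(v, 1) for k, v in avlt.items()},
    })
    table.attrs["link"] = {
        "beta": m.link_beta,
        "age_beta": m.link_age_beta,
        "education_beta": m.link_education_beta,
        "noise_sd": m.link_noise_sd,
    }
    return table
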