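"""Monte-Carlo validation experiments for the whole pipeline.

Each function runs the synthetic generator through the relevant pipeline
stages many times and measures an operating characteristic: the type-I
error of the permutation test under a true null, the fraction of control
networks showing the small-world signature, and the recovery rate /
family-wise error of the network-based statistic against an implanted
lesion. They serve the test suite and the reproduction script; problem
sizes are arguments so callers choose their own precision/runtime
trade-off.
"""
from __future__ import annotations

import numpy as np

from . import metrics as gm
from .inference import nbs, permutation_test
from .network import pearson_connectivity, sweep, threshold_by_sparsity, default_sparsity_grid
from .synthetic import GroundTruthNetwork, SimulationConfig, make_ground_truth, simulate_timeseries

__all__ = [
    "eglob_auc_per_subject",
    "null_type1_error",
    "smallworld_rate",
    "nbs_recovery_rate",
    "nbs_null_fwer",
]


def eglob_auc_per_subject(ts, grid=None) -> tuple:
    """Global-efficiency AUC over the sparsity sweep, split by group.

    Returns (patient values, control values) in subject order.
    """
    grid = default_sparsity_grid() if grid is None else np.asarray(grid)
    pat, ctl = [], []
    for s in ts.subjects:
        c = pearson_connectivity(s)
        curve = [gm.global_efficiency(a) for _, a in sweep(c, grid)]
        val = gm.auc(np.array(curve), grid)
        (pat if s.group == "patient" else ctl).append(val)
    return np.array(pat), np.array(ctl)


def null_type1_error(
    n_replicates: int = 200,
    n_perm: int = 999,
    seed: int | None = None,
    cfg: SimulationConfig | None = None,
    grid=None,
) -> float:
    """Empirical type-I error of the one-tailed AUC permutation test.

    Both groups are drawn from the identical distribution (effect size
    zero), the global-efficiency AUC computed per subject, and the
    randomised-reallocation test applied at the 95th-percentile critical
    value. Returns the fraction of replicates rejecting; under a correct
    test this sits near the nominal 0.05.
    """
    rng = np.random.default_rng(seed)
    gt = make_ground_truth(n_affected_edges=0, seed=int(rng.integers(2**31)))
    base = cfg or SimulationConfig()
    grid = default_sparsity_grid() if grid is None else np.asarray(grid)
    rejections = 0
    for _ in range(n_replicates):
        rep_cfg = SimulationConfig(
            n_patients=base.n_patients, n_controls=base.n_controls,
            n_timepoints=base.n_timepoints, tr_seconds=base.tr_seconds,
            band=base.band, edge_corr=base.edge_corr, noise_sd=base.noise_sd,
            seed=int(rng.integers(2**31)),
        )
        ts = simulate_timeseries(gt, rep_cfg)
        pat, ctl = eglob_auc_per_subject(ts, grid)
        res = permutation_test(pat, ctl, n_perm=n_perm, alternative="greater",
                               seed=int(rng.integers(2**31)))
        rejections += int(res.reject)
    return rejections / n_replicates


def smallworld_rate(
    n_replicates: int = 20,
    sparsity: float = 0.15,
    n_random: int = 20,
    seed: int | None = None,
) -> float:
    """Fraction of simulated control networks showing the small-world signature.

    One control subject is simulated per replicate, thresholded at the
    given sparsity, and gamma/lambda computed against a degree-preserving
    ensemble; "signature" means gamma > 1 with lambda in [0.8, 1.2].
    """
    rng = np.random.default_rng(seed)
    gt = make_ground_truth(n_affected_edges=0, seed=int(rng.integers(2**31)))
    hits = 0
    for _ in range(n_replicates):
        cfg = SimulationConfig(n_patients=1, n_controls=1,
                               seed=int(rng.integers(2**31)))
        ts = simulate_timeseries(gt, cfg)
        ctl = next(s for s in ts.subjects if s.group == "control")
        a = threshold_by_sparsity(pearson_connectivity(ctl), sparsity)
        spec = gm.RandomEnsembleSpec(n_random=n_random, seed=int(rng.integers(2**31)))
        ensemble = gm.degree_preserving_randomize(a, spec)
        gamma, lam, _ = gm.normalized_smallworld(a, ensemble)
        hits += int(gamma > 1.0 and 0.8 <= lam <= 1.2)
    return hits / n_replicates


def _simulate_fc_stacks(gt: GroundTruthNetwork, cfg: SimulationConfig):
    ts = simulate_timeseries(gt, cfg)
    pat = np.stack([pearson_connectivity(s) for s in ts.subjects if s.group == "patient"])
    ctl = np.stack([pearson_connectivity(s) for s in ts.subjects if s.group == "control"])
    return pat, ctl


def nodal_auc_per_subject(ts, grid=None) -> tuple:
    """Per-subject AUCs of the three nodal metrics, split by group.

    Returns (patients, controls) as arrays of shape (n_subjects,
    3 * n_regions), columns ordered metric-major (degree block, then
    nodal efficiency, then betweenness).
    """
    grid = default_sparsity_grid() if grid is None else np.asarray(grid)
    pat, ctl = [], []
    for s in ts.subjects:
        c = pearson_connectivity(s)
        curves = {m: [] for m in gm.NODAL_METRIC_NAMES}
        for _, a in sweep(c, grid):
            nod = gm.nodal_metrics(a)
            for m in gm.NODAL_METRIC_NAMES:
                curves[m].append(nod[m])
        vals = np.concatenate([
            np.trapezoid(np.asarray(curves[m]), grid, axis=0)
            for m in gm.NODAL_METRIC_NAMES
        ])
        (pat if s.group == "patient" else ctl).append(vals)
    return np.asarray(pat), np.asarray(ctl)


def screen_nodes(ts, grid=None, alpha: float = 0.05, n_perm: int = 199,
                 seed: int | None = None) -> np.ndarray:
    """Regions significant at ``alpha`` in >= 1 of the 3 nodal AUC tests.

    This is the node-selection rule used before the masked network-based
    statistic: a region enters the mask when the one-tailed permutation
    test on any of its nodal degree, efficiency or betweenness AUCs falls
    below ``alpha``.
    """
    from .inference import permutation_test_many

    pat, ctl = nodal_auc_per_subject(ts, grid)
    res = permutation_test_many(pat, ctl, n_perm=n_perm, seed=seed)
    n_regions = pat.shape[1] // len(gm.NODAL_METRIC_NAMES)
    p = res["p_value"].to_numpy().reshape(len(gm.NODAL_METRIC_NAMES), n_regions)
    return np.nonzero((p < alpha).any(axis=0))[0]


def nbs_recovery_rate(
    n_replicates: int = 5,
    effect_size: float = 0.4,
    n_affected_edges: int = 13,
    threshold: float = 2.441,
    n_perm: int = 499,
    screening_n_perm: int = 199,
    min_edge_recall: float = 0.9,
    n_patients: int = 12,
    n_controls: int = 24,
    n_timepoints: int = 229,
    seed: int | None = None,
    two_stage: bool = True,
) -> float:
    """Fraction of replicates in which the implanted lesion is recovered.

    Each replicate implants a connected subnetwork of
    ``n_affected_edges`` edges weakened by ``effect_size`` in the patient
    group, then runs the two-stage procedure: nodal-metric screening
    selects a region mask, and the network-based statistic is applied to
    the connectivity submatrix induced on that mask (``two_stage=False``
    skips screening and analyses the whole network). A replicate counts
    as a success when the union of significant components (p < 0.05)
    contains at least ``min_edge_recall`` of the implanted edges.

    Group sizes and scan length are exposed because recovery power
    depends strongly on them; see the methods documentation for why
    study-sized designs detect this lesion only rarely.
    """
    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_replicates):
        gt = make_ground_truth(n_affected_edges=n_affected_edges,
                               effect_size=effect_size,
                               seed=int(rng.integers(2**31)))
        cfg = SimulationConfig(n_patients=n_patients, n_controls=n_controls,
                               n_timepoints=n_timepoints,
                               seed=int(rng.integers(2**31)))
        ts = simulate_timeseries(gt, cfg)
        mask = None
        if two_stage:
            mask = screen_nodes(ts, n_perm=screening_n_perm,
                                seed=int(rng.integers(2**31)))
        pat = np.stack([pearson_connectivity(s) for s in ts.subjects
                        if s.group == "patient"])
        ctl = np.stack([pearson_connectivity(s) for s in ts.subjects
                        if s.group == "control"])
        if mask is not None and mask.size == 0:
            continue  # nothing screened in: no recovery this replicate
        res = nbs(pat, ctl, threshold=threshold, n_perm=n_perm,
                  seed=int(rng.integers(2**31)), node_mask=mask)
        found = {e for c in res.significant for e in c.edges}
        truth = {tuple(sorted(e)) for e in gt.affected_edges}
        recall = len(found & truth) / len(truth)
        successes += int(recall >= min_edge_recall)
    return successes / n_replicates


def nbs_null_fwer(
    n_replicates: int = 100,
    threshold: float = 2.441,
    n_perm: int = 199,
    seed: int | None = None,
) -> float:
    """Family-wise error of NBS under the global null.

    Both groups are simulated identically; returns the fraction of
    replicates reporting any component with p < 0.05 (weak FWER control
    should keep this near 0.05).
    """
    rng = np.random.default_rng(seed)
    gt = make_ground_truth(n_affected_edges=0, seed=int(rng.integers(2**31)))
    hits = 0
    for _ in range(n_replicates):
        cfg = SimulationConfig(seed=int(rng.integers(2**31)))
        pat, ctl = _simulate_fc_stacks(gt, cfg)
        res = nbs(pat, ctl, threshold=threshold, n_perm=n_perm,
                  seed=int(rng.integers(2**31)))
        hits += int(len(res.significant) > 0)
    return hits / n_replicates
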