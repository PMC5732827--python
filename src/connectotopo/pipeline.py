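"""End-to-end orchestration: simulate-or-load -> preprocess -> networks ->
metrics -> group statistics -> report, under one serialisable config.

A run writes every stage's tables under the output directory plus a
``manifest.json`` recording the resolved configuration, package version,
SHA-256 checksums of the outputs and any warnings raised, so a rerun with
the same config reproduces deterministic outputs bit-identically and
seeded stochastic outputs exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import metrics as gm
from .dataset import RoiTimeSeriesSet
from .inference import metric_behavior_regression, nbs, permutation_test_many
from .io import (dump_yaml_config, load_yaml_config, read_centroids,
                 read_timeseries_dir, write_connectivity, write_timeseries_dir)
from .inference import edge_distance_classify
from .network import pearson_connectivity, sweep
from .preprocess import preprocess
from .synthetic import SimulationConfig, make_ground_truth, simulate_timeseries

__all__ = ["RunConfig", "RunManifest", "run_all", "compute_metric_profiles"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    Defaults mirror the emulated study: 10 discarded volumes, 0.01-0.08 Hz
    band, sparsity 0.10-0.34 step 0.01, ensemble of 100 degree-preserving
    random networks, 10,000 permutations, NBS primary threshold 2.441 and
    a 75 mm long-range cutoff. Reduce ``n_perm``/``n_random``/grid for
    exploratory runs.
    """

    input_dir: str | None = None       # load a dataset; None -> simulate
    output_dir: str = "connectotopo_out"
    seed: int = 0
    # simulation
    n_nodes: int = 90
    ws_k: int = 8
    ws_p: float = 0.1
    n_affected_edges: int = 13
    effect_size: float = 0.2
    n_patients: int = 12
    n_controls: int = 24
    n_timepoints_raw: int = 239        # before discarding
    tr_seconds: float = 2.0
    edge_corr: float = 0.3
    noise_sd: float = 0.0
    # preprocessing
    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    filter_order: int = 4
    # networks
    sparsity_min: float = 0.10
    sparsity_max: float = 0.34
    sparsity_step: float = 0.01
    absolute_ranking: bool = False
    # metrics
    n_random: int = 100
    rewires_per_edge: int = 10
    path_length_convention: str = "reachable"
    # statistics
    n_perm: int = 10000
    nbs_threshold: float = 2.441
    cutoff_mm: float = 75.0
    centroids_file: str | None = None
    regression_metrics: tuple = ("path_length", "global_efficiency")

    def sparsity_grid(self) -> np.ndarray:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step)) + 1
        return np.round(np.linspace(self.sparsity_min, self.sparsity_max, n),
                        10)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = load_yaml_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "regression_metrics" in raw:
            raw["regression_metrics"] = tuple(raw["regression_metrics"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["regression_metrics"] = list(d["regression_metrics"])
        dump_yaml_config(d, path)


@dataclass
class RunManifest:
    config: dict
    version: str
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "checksums": self.checksums,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def compute_metric_profiles(ts: RoiTimeSeriesSet, cfg: RunConfig) -> tuple:
    """Per-subject global/nodal metric curves and AUCs across the sweep.

    Returns (global long-format frame, nodal long-format frame,
    global AUC frame, nodal AUC frame, fc stack dict by group).
    """
    grid = cfg.sparsity_grid()
    rng = np.random.default_rng(cfg.seed)
    glob_rows, nodal_rows = [], []
    fc = {"patient": [], "control": []}
    for s in ts.subjects:
        c = pearson_connectivity(s)
        fc[s.group].append(c)
        graphs = sweep(c, grid, absolute=cfg.absolute_ranking)
        for sp, a in graphs:
            spec = gm.RandomEnsembleSpec(
                n_random=cfg.n_random,
                rewires_per_edge=cfg.rewires_per_edge,
                seed=int(rng.integers(2**31)),
            )
            ensemble = gm.degree_preserving_randomize(a, spec)
            vals = gm.global_metrics(a, ensemble, convention=cfg.path_length_convention)
            if vals["unreachable_fraction"] > 0:
                log.info("subject %s sparsity %.2f: %.1f%% node pairs unreachable",
                         s.subject_id, sp, 100 * vals["unreachable_fraction"])
            for m in gm.GLOBAL_METRIC_NAMES:
                glob_rows.append((s.subject_id, s.group, float(sp), m, vals[m]))
            nod = gm.nodal_metrics(a)
            for m in gm.NODAL_METRIC_NAMES:
                for node, v in enumerate(nod[m]):
                    nodal_rows.append((s.subject_id, s.group, float(sp), m,
                                       node + 1, float(v)))
    glob = pd.DataFrame(glob_rows, columns=["subject_id", "group", "sparsity",
                                            "metric", "value"])
    nodal = pd.DataFrame(nodal_rows, columns=["subject_id", "group", "sparsity",
                                              "metric", "region_id", "value"])

    def _auc_frame(frame, keys):
        out = []
        for key, grp in frame.groupby(keys, sort=True):
            grp = grp.sort_values("sparsity")
            out.append((*key, gm.auc(grp["value"].to_numpy(), grp["sparsity"].to_numpy())))
        return pd.DataFrame(out, columns=[*keys, "auc"])

    glob_auc = _auc_frame(glob, ["subject_id", "group", "metric"])
    nodal_auc = _auc_frame(nodal, ["subject_id", "group", "metric", "region_id"])
    fc_stacks = {g: np.stack(v) for g, v in fc.items() if v}
    return glob, nodal, glob_auc, nodal_auc, fc_stacks


def run_all(cfg: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all tables plus a manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    caught: list = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # --- stage 1: simulate or load -----------------------------------
        if cfg.input_dir is None:
            gt = make_ground_truth(
                n_nodes=cfg.n_nodes, k=cfg.ws_k, p=cfg.ws_p,
                n_affected_edges=cfg.n_affected_edges,
                effect_size=cfg.effect_size, seed=int(rng.integers(2**31)),
            )
            sim = SimulationConfig(
                n_patients=cfg.n_patients, n_controls=cfg.n_controls,
                n_timepoints=cfg.n_timepoints_raw, tr_seconds=cfg.tr_seconds,
                band=(cfg.band_low_hz, cfg.band_high_hz),
                edge_corr=cfg.edge_corr, noise_sd=cfg.noise_sd,
                seed=int(rng.integers(2**31)),
            )
            ts = simulate_timeseries(gt, sim)
            write_timeseries_dir(ts, out / "dataset", ground_truth=gt)
        else:
            ts = read_timeseries_dir(cfg.input_dir)

        # --- stage 2: preprocessing --------------------------------------
        ts = preprocess(ts, n_discard=cfg.n_discard, low_hz=cfg.band_low_hz,
                        high_hz=cfg.band_high_hz, filter_order=cfg.filter_order)

        # --- stage 3 + 4: networks and metrics ---------------------------
        glob, nodal, glob_auc, nodal_auc, fc_stacks = compute_metric_profiles(ts, cfg)
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for s in ts.subjects:
            write_connectivity(pearson_connectivity(s),
                               conn_dir / f"sub-{s.subject_id}_fc.tsv")
        glob.to_csv(out / "global_metrics.tsv", sep="\t", index=False)
        nodal.to_csv(out / "nodal_metrics.tsv", sep="\t", index=False)
        glob_auc.to_csv(out / "global_auc.tsv", sep="\t", index=False)
        nodal_auc.to_csv(out / "nodal_auc.tsv", sep="\t", index=False)

        # --- stage 5: group statistics -----------------------------------
        def _pivot(auc_frame, keys):
            return auc_frame.pivot_table(index="subject_id", columns=keys,
                                         values="auc", sort=True)

        pat_ids = ts.group_ids("patient")
        ctl_ids = ts.group_ids("control")

        gw = _pivot(glob_auc, "metric")
        stats_glob = permutation_test_many(
            gw.loc[pat_ids].to_numpy(), gw.loc[ctl_ids].to_numpy(),
            n_perm=cfg.n_perm, seed=int(rng.integers(2**31)),
        )
        stats_glob.insert(0, "metric", list(gw.columns))
        stats_glob.to_csv(out / "global_stats.tsv", sep="\t", index=False)

        nw = _pivot(nodal_auc, ["metric", "region_id"])
        stats_nodal = permutation_test_many(
            nw.loc[pat_ids].to_numpy(), nw.loc[ctl_ids].to_numpy(),
            n_perm=cfg.n_perm, seed=int(rng.integers(2**31)),
        )
        stats_nodal.insert(0, "metric", [m for m, _ in nw.columns])
        stats_nodal.insert(1, "region_id", [r for _, r in nw.columns])
        stats_nodal.to_csv(out / "nodal_stats.tsv", sep="\t", index=False)

        # --- stage 6: NBS -------------------------------------------------
        res = nbs(fc_stacks["patient"], fc_stacks["control"],
                  threshold=cfg.nbs_threshold, n_perm=cfg.n_perm,
                  seed=int(rng.integers(2**31)))
        mean_diff = (np.arctanh(np.clip(fc_stacks["patient"], -0.999999, 0.999999)).mean(axis=0)
                     - np.arctanh(np.clip(fc_stacks["control"], -0.999999, 0.999999)).mean(axis=0))
        nbs_payload = {
            "threshold": res.threshold,
            "n_perm": res.n_perm,
            "components": [
                {"nodes": [n + 1 for n in c.nodes],
                 "edges": [[i + 1, j + 1] for i, j in c.edges],
                 "size_edges": c.size_edges,
                 "p_value": c.p_value}
                for c in res.components
            ],
        }
        (out / "nbs_result.json").write_text(json.dumps(nbs_payload, indent=1))

        # distance classification (only when a centroid table is supplied)
        if cfg.centroids_file is not None:
            cents = read_centroids(cfg.centroids_file)
            sig_edges = [e for c in res.significant for e in c.edges]
            findings = edge_distance_classify(
                [(i + 1, j + 1) for i, j in sig_edges],
                cents,
                cutoff_mm=cfg.cutoff_mm,
                fc_differences=[mean_diff[i, j] for i, j in sig_edges],
            )
            pd.DataFrame([dataclasses.asdict(f) for f in findings]).to_csv(
                out / "edge_findings.tsv", sep="\t", index=False)

        # --- stage 7: metric-cognition regression -------------------------
        part = ts.participants_frame().set_index("subject_id")
        reg_rows = []
        for metric in cfg.regression_metrics:
            vals = gw.loc[pat_ids, metric]
            tab = part.loc[pat_ids, ["age", "sex", "education", "mmse"]].copy()
            tab[metric] = vals
            try:
                rr = metric_behavior_regression(tab, metric, "mmse")
                reg_rows.append((metric, "mmse", rr.metric_coefficient,
                                 rr.metric_p_value, rr.adjusted_r_squared, rr.n))
            except (KeyError, ValueError) as exc:
                log.warning("regression on %s skipped: %s", metric, exc)
        if reg_rows:
            pd.DataFrame(reg_rows, columns=["metric", "score", "coefficient",
                                            "p_value", "adjusted_r2", "n"]
                         ).to_csv(out / "regression.tsv", sep="\t", index=False)

        caught = [str(w.message) for w in wrec]

    cfg.to_yaml(out / "config.yaml")
    manifest = RunManifest(config=dataclasses.asdict(cfg), version=__version__,
                           warnings=caught)
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[str(f.relative_to(out))] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest
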