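"""On-disk formats: subject time-series TSVs, participants table,
ground-truth JSON, centroid tables and YAML configs.

Conventions: one ``sub-<id>_ts.tsv`` per subject (tab-separated, no
header, rows = time points, columns = regions); ``participants.tsv`` with
a header row; region ids are 1-based AAL numbering externally and 0-based
internally, converted only here.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import RoiTimeSeriesSet, Subject
from .synthetic import GroundTruthNetwork

__all__ = [
    "write_timeseries_dir",
    "read_timeseries_dir",
    "write_ground_truth",
    "read_ground_truth",
    "read_centroids",
    "write_connectivity",
    "read_connectivity",
    "write_edge_list",
    "load_yaml_config",
    "dump_yaml_config",
]


def write_timeseries_dir(ts: RoiTimeSeriesSet, out_dir, ground_truth: GroundTruthNetwork | None = None) -> Path:
    """Write one TSV per subject plus participants.tsv (and ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in ts.subjects:
        np.savetxt(out / f"sub-{s.subject_id}_ts.tsv", s.data, delimiter="\t", fmt="%.10g")
        if s.nuisance is not None:
            np.savetxt(out / f"sub-{s.subject_id}_nuisance.tsv", s.nuisance,
                       delimiter="\t", fmt="%.10g")
    frame = ts.participants_frame()
    frame.insert(2, "tr_seconds", ts.tr_seconds)
    frame.to_csv(out / "participants.tsv", sep="\t", index=False)
    if ground_truth is not None:
        write_ground_truth(ground_truth, out / "ground_truth.json")
    return out


def read_timeseries_dir(path) -> RoiTimeSeriesSet:
    """Load a dataset directory; fail loudly on structural problems."""
    root = Path(path)
    part_file = root / "participants.tsv"
    if not part_file.exists():
        raise FileNotFoundError(f"{part_file} not found")
    table = pd.read_csv(part_file, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in table.columns or "group" not in table.columns:
        raise ValueError(f"{part_file}: needs subject_id and group columns")
    tr = float(table["tr_seconds"].iloc[0]) if "tr_seconds" in table.columns else 2.0

    subjects = []
    n_regions = None
    for _, row in table.iterrows():
        sid = row["subject_id"]
        f = root / f"sub-{sid}_ts.tsv"
        if not f.exists():
            raise FileNotFoundError(f"participants.tsv lists subject {sid} but {f} is missing")
        try:
            data = np.loadtxt(f, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{f}: malformed time-series file ({exc})") from exc
        if np.isnan(data).any():
            bad = int(np.argwhere(np.isnan(data))[0][0]) + 1
            raise ValueError(f"{f}: NaN value at row {bad}")
        if n_regions is None:
            n_regions = data.shape[1]
        elif data.shape[1] != n_regions:
            raise ValueError(
                f"{f}: {data.shape[1]} regions, expected {n_regions}"
            )
        nuis_file = root / f"sub-{sid}_nuisance.tsv"
        nuisance = np.loadtxt(nuis_file, delimiter="\t", ndmin=2) if nuis_file.exists() else None
        covars = {
            c: row[c] for c in table.columns
            if c not in ("subject_id", "group", "tr_seconds")
        }
        subjects.append(Subject(subject_id=sid, data=data, group=row["group"],
                                covariates=covars, nuisance=nuisance))
    return RoiTimeSeriesSet(subjects, tr_seconds=tr)


def write_ground_truth(gt: GroundTruthNetwork, path) -> None:
    iu, ju = np.nonzero(np.triu(gt.adjacency, k=1))
    payload = {
        "n_nodes": gt.n_nodes,
        "k": gt.k,
        "p": gt.p,
        "effect_size": gt.effect_size,
        "edges": [[int(i) + 1, int(j) + 1] for i, j in zip(iu, ju)],  # 1-based
        "affected_edges": [[int(i) + 1, int(j) + 1] for i, j in gt.affected_edges],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruthNetwork:
    payload = json.loads(Path(path).read_text())
    n = payload["n_nodes"]
    a = np.zeros((n, n))
    for i, j in payload["edges"]:
        a[i - 1, j - 1] = a[j - 1, i - 1] = 1.0
    return GroundTruthNetwork(
        n_nodes=n, adjacency=a, k=payload["k"], p=payload["p"],
        affected_edges=tuple((i - 1, j - 1) for i, j in payload["affected_edges"]),
        effect_size=payload["effect_size"],
    )


def read_centroids(path) -> pd.DataFrame:
    """Atlas centroid table: region_id <TAB> name <TAB> x <TAB> y <TAB> z (mm)."""
    t = pd.read_csv(path, sep="\t")
    required = {"region_id", "name", "x", "y", "z"}
    if not required.issubset(t.columns):
        raise ValueError(f"centroid table needs columns {sorted(required)}")
    if t["region_id"].duplicated().any():
        raise ValueError("duplicate region ids in centroid table")
    if not np.isfinite(t[["x", "y", "z"]].to_numpy()).all():
        raise ValueError("non-finite centroid coordinates")
    return t


def write_connectivity(c: np.ndarray, path) -> None:
    np.savetxt(path, c, delimiter="\t", fmt="%.10g")


def read_connectivity(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_edge_list(adjacency: np.ndarray, path) -> None:
    """Edge list TSV, 1-based region indices, one ``i<TAB>j`` row per edge."""
    iu, ju = np.nonzero(np.triu(adjacency, k=1))
    with open(path, "w") as fh:
        fh.write("region_a\tregion_b\n")
        for i, j in zip(iu, ju):
            fh.write(f"{i + 1}\t{j + 1}\n")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
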