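"""Correlation matrices and sparsity-thresholded binary graphs.

A subject's functional network is the Pearson correlation between every
pair of region signals, binarised by *sparsity*: at sparsity S the
strongest S fraction of all possible edges is kept, so every subject's
graph has the same edge count and group comparisons are not confounded by
overall connectivity strength. The analysis sweeps S over a grid (default
0.10-0.34 in steps of 0.01) and later integrates each metric curve over
the sweep.

Ranking is over raw signed correlation by default (strongest positive
first), matching the common toolbox convention for binary sparsity
networks; pass ``absolute=True`` to rank |r| instead. Edge counts use
round-half-away-from-zero of S*n(n-1)/2 and ties in r break by
lexicographic (i, j) order, so thresholding is deterministic across
platforms. Edge sets are nested along the grid by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Subject

__all__ = [
    "pearson_connectivity",
    "threshold_by_sparsity",
    "sweep",
    "default_sparsity_grid",
    "ThresholdedGraphSet",
]


def default_sparsity_grid() -> np.ndarray:
    """The standard sweep: 0.10 to 0.34 inclusive, step 0.01 (25 values)."""
    return np.round(np.linspace(0.10, 0.34, 25), 2)


def pearson_connectivity(subject_or_array) -> np.ndarray:
    """Sample Pearson correlation between every pair of region signals.

    Returns a symmetric (n_regions x n_regions) matrix with the diagonal
    set to 0 (self-correlations never participate in edge ranking). A
    zero-variance region makes its correlations undefined and raises.
    """
    x = subject_or_array.data if isinstance(subject_or_array, Subject) else np.asarray(subject_or_array, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a (time x region) array with >= 3 time points")
    sd = x.std(axis=0)
    dead = np.nonzero(sd == 0.0)[0]
    if dead.size:
        raise ValueError(f"zero-variance region signal(s) at column(s) {dead.tolist()}")
    c = np.corrcoef(x, rowvar=False)
    c = 0.5 * (c + c.T)  # enforce exact symmetry against float round-off
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 0.0)
    return c


def _edge_count(n: int, sparsity: float) -> int:
    m_all = n * (n - 1) // 2
    return int(np.floor(sparsity * m_all + 0.5))  # round half away from zero


def _ranked_edges(c: np.ndarray, absolute: bool) -> tuple:
    """Upper-triangle edges ordered strongest-first, ties by (i, j)."""
    n = c.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(c[iu, ju]) if absolute else c[iu, ju]
    order = np.lexsort((ju, iu, -vals))  # primary: value desc; then i, j asc
    return iu[order], ju[order]


def threshold_by_sparsity(c: np.ndarray, sparsity: float, absolute: bool = False) -> np.ndarray:
    """Binary adjacency keeping the top round(S*n(n-1)/2) edges of ``c``."""
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    if c.shape != (n, n):
        raise ValueError("connectivity matrix must be square")
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    m = _edge_count(n, sparsity)
    iu, ju = _ranked_edges(c, absolute)
    if m > iu.size:
        raise ValueError(f"requested {m} edges but only {iu.size} pairs exist")
    a = np.zeros((n, n))
    a[iu[:m], ju[:m]] = 1.0
    return a + a.T


@dataclass
class ThresholdedGraphSet:
    """One subject's binary graphs across the sparsity sweep (nested)."""

    sparsity_grid: np.ndarray
    adjacencies: list  # one (n, n) binary array per grid value

    def __post_init__(self) -> None:
        if len(self.adjacencies) != len(self.sparsity_grid):
            raise ValueError("one adjacency required per sparsity value")

    @property
    def n_nodes(self) -> int:
        return self.adjacencies[0].shape[0]

    def __iter__(self):
        return iter(zip(self.sparsity_grid, self.adjacencies))


def sweep(c: np.ndarray, sparsity_grid: np.ndarray | None = None, absolute: bool = False) -> ThresholdedGraphSet:
    """Threshold one connectivity matrix at every sparsity of the grid.

    The same edge ranking is reused for the whole grid, which guarantees
    the nestedness invariant: the edge set at a smaller sparsity is a
    subset of the edge set at any larger one.
    """
    grid = default_sparsity_grid() if sparsity_grid is None else np.asarray(sparsity_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be non-empty and strictly increasing")
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    iu, ju = _ranked_edges(c, absolute)
    adjacencies = []
    for s in grid:
        m = _edge_count(n, float(s))
        if m > iu.size:
            raise ValueError(f"sparsity {s} requests {m} edges but only {iu.size} pairs exist")
        a = np.zeros((n, n))
        a[iu[:m], ju[:m]] = 1.0
        adjacencies.append(a + a.T)
    return ThresholdedGraphSet(sparsity_grid=grid, adjacencies=adjacencies)
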