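"""The ten network metrics, random-network normalisation, and AUC.

Global metrics (seven): mean clustering coefficient C_p, characteristic
path length L_p, global efficiency E_glob, local efficiency E_loc, and the
small-world trio gamma = C_p / <C_p^rand>, lambda = L_p / <L_p^rand>,
sigma = gamma / lambda, where <.> averages a degree-preserving random
ensemble. Nodal metrics (three): degree, nodal efficiency (mean inverse
distance to every other node) and normalised shortest-path betweenness.
A metric's curve over the sparsity sweep is aggregated into a single
trapezoidal area under the curve (AUC), removing single-threshold
dependence.

Conventions for the degenerate cases a sparse threshold can produce:
nodes with degree < 2 contribute 0 to C_p and E_loc (and stay in the
mean, keeping AUCs comparable across subjects); L_p averages over
*reachable* pairs only and the unreachable fraction is reported alongside
(a harmonic-mean convention, L_p = 1/E_glob, is available via
``characteristic_path_length(..., convention="harmonic")``). Betweenness
is normalised by (n-1)(n-2)/2.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "clustering_coefficient",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_metrics",
    "RandomEnsembleSpec",
    "degree_preserving_randomize",
    "normalized_smallworld",
    "auc",
    "global_metrics",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

log = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = ("clustering", "path_length", "global_efficiency",
                       "local_efficiency", "gamma", "lambda", "sigma")
NODAL_METRIC_NAMES = ("degree", "nodal_efficiency", "betweenness")


def clustering_coefficient(a: np.ndarray) -> tuple:
    """Per-node clustering and its mean C_p.

    c_i = 2 t_i / (k_i (k_i - 1)) with t_i the number of triangles through
    node i; nodes with k_i < 2 get 0.
    """
    a = np.asarray(a, dtype=float)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1.0), 0.0)
    return c, float(c.mean())


def shortest_path_lengths(a: np.ndarray) -> np.ndarray:
    """Pairwise hop-distance matrix (BFS); unreachable pairs are inf."""
    a = np.asarray(a, dtype=float)
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def characteristic_path_length(
    a: np.ndarray, convention: str = "reachable"
) -> tuple:
    """L_p and the fraction of unreachable node pairs.

    ``convention="reachable"`` averages hop distance over reachable
    unordered pairs; ``"harmonic"`` returns 1 / E_glob, which penalises
    disconnection instead of ignoring it.
    """
    d = shortest_path_lengths(a)
    n = d.shape[0]
    if n < 2:
        raise ValueError("characteristic path length needs >= 2 nodes")
    iu = np.triu_indices(n, k=1)
    dv = d[iu]
    finite = np.isfinite(dv)
    unreachable_fraction = float(1.0 - finite.mean())
    if convention == "harmonic":
        eg = global_efficiency(a)
        if eg == 0.0:
            raise ValueError("harmonic path length undefined: no reachable pairs")
        return 1.0 / eg, unreachable_fraction
    if convention != "reachable":
        raise ValueError(f"unknown convention {convention!r}")
    if not finite.any():
        raise ValueError("no reachable node pairs: path length undefined")
    if unreachable_fraction > 0:
        log.debug("L_p computed over reachable pairs only; %.1f%% unreachable",
                  100 * unreachable_fraction)
    return float(dv[finite].mean()), unreachable_fraction


def global_efficiency(a: np.ndarray) -> float:
    """Mean inverse hop distance over unordered pairs (1/inf = 0)."""
    d = shortest_path_lengths(a)
    n = d.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    return float(np.where(np.isfinite(inv), inv, 0.0).mean())


def local_efficiency(a: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbourhood.

    The neighbourhood of node i is the subgraph induced on its neighbours;
    nodes with < 2 neighbours contribute 0.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if nbrs.size >= 2:
            total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


def _nodal_efficiency(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def nodal_metrics(a: np.ndarray) -> dict:
    """Degree, nodal efficiency and normalised betweenness per node.

    Betweenness is Brandes shortest-path betweenness divided by
    (n-1)(n-2)/2, so a star's centre scores exactly 1.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if n < 3:
        raise ValueError("nodal metrics need >= 3 nodes")
    d = shortest_path_lengths(a)
    g = nx.from_numpy_array(a)
    bet = nx.betweenness_centrality(g, normalized=True)
    return {
        "degree": a.sum(axis=1),
        "nodal_efficiency": _nodal_efficiency(d),
        "betweenness": np.array([bet[i] for i in range(n)]),
    }


@dataclass(frozen=True)
class RandomEnsembleSpec:
    """Degree-preserving null ensemble: size, rewiring effort, seed."""

    n_random: int = 100
    rewires_per_edge: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_random < 1 or self.rewires_per_edge < 1:
            raise ValueError("n_random and rewires_per_edge must be >= 1")


def degree_preserving_randomize(a: np.ndarray, spec: RandomEnsembleSpec) -> list:
    """Ensemble of rewired graphs with the input's exact degree sequence.

    Double-edge-swap rewiring, ``rewires_per_edge * |E|`` accepted swaps
    per member; swaps creating self-loops or multi-edges are rejected by
    construction. Connectedness is *not* enforced (enforcing it biases
    the null). If the swap quota is unreachable (e.g. a star graph) the
    member is returned as-is with a warning.
    """
    a = np.asarray(a, dtype=float)
    g0 = nx.from_numpy_array(a)
    n_edges = g0.number_of_edges()
    if n_edges < 2:
        raise ValueError("randomization needs >= 2 edges")
    rng = np.random.default_rng(spec.seed)
    nswap = spec.rewires_per_edge * n_edges
    out = []
    for _ in range(spec.n_random):
        g = g0.copy()
        try:
            nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXAlgorithmError:
            warnings.warn(
                f"swap quota {nswap} unreachable; keeping partially rewired graph",
                stacklevel=2,
            )
        out.append(nx.to_numpy_array(g, nodelist=range(a.shape[0]), dtype=float))
    return out


def normalized_smallworld(a: np.ndarray, ensemble: list) -> tuple:
    """gamma, lambda, sigma of ``a`` against a random ensemble.

    gamma = C_p / mean C_p(ensemble); lambda = L_p / mean L_p(ensemble);
    sigma = gamma / lambda (exactly, as returned).
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    _, cp = clustering_coefficient(a)
    lp, _ = characteristic_path_length(a)
    cp_rand = np.mean([clustering_coefficient(r)[1] for r in ensemble])
    lp_rand = np.mean([characteristic_path_length(r)[0] for r in ensemble])
    if cp_rand == 0.0 or lp_rand == 0.0:
        raise ValueError("ensemble mean clustering/path length is zero")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return gamma, lam, gamma / lam


def auc(values: np.ndarray, sparsity_grid: np.ndarray) -> float:
    """Trapezoidal integral of a metric curve over the sparsity grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(sparsity_grid, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(
            f"curve length {values.shape} does not match grid {grid.shape}"
        )
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 knots")
    return float(np.trapezoid(values, grid))


def global_metrics(a: np.ndarray, ensemble: list | None = None,
                   convention: str = "reachable") -> dict:
    """All seven global metrics of one graph (gamma/lambda/sigma need an ensemble)."""
    _, cp = clustering_coefficient(a)
    lp, unreachable = characteristic_path_length(a, convention=convention)
    vals = {
        "clustering": cp,
        "path_length": lp,
        "global_efficiency": global_efficiency(a),
        "local_efficiency": local_efficiency(a),
        "unreachable_fraction": unreachable,
    }
    if ensemble is not None:
        gamma, lam, sigma = normalized_smallworld(a, ensemble)
        vals.update({"gamma": gamma, "lambda": lam, "sigma": sigma})
    return vals
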