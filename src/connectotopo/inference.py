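"""Group-level statistics: permutation tests, the network-based statistic,
distance-based connection classification and metric-cognition regression.

Group differences in metric AUCs are assessed with one-tailed
non-parametric permutation tests: group labels are randomly reallocated
(group sizes fixed), the mean difference recomputed each time, and the
95th percentile of the null distribution used as the critical value at a
nominal type-I error of 0.05. P-values carry the +1 finite-permutation
correction, p = (#{null >= observed} + 1) / (n_perm + 1), so p = 0 is
impossible. An exhaustive-enumeration mode replaces sampling with all
label splits on small samples.

Edge-wise inference uses the network-based statistic (NBS): a two-sample
t statistic per edge (on Fisher z-transformed correlations by default), a
primary threshold T on |t|, and a permutation null for the size in edges
of the largest connected suprathreshold component, giving weak
family-wise error control over components.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "PermutationResult",
    "permutation_test",
    "permutation_test_many",
    "edge_t_matrix",
    "NbsComponent",
    "NbsResult",
    "nbs",
    "component_summary",
    "EdgeFinding",
    "edge_distance_classify",
    "RegressionResult",
    "metric_behavior_regression",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# permutation tests on scalar metrics

@dataclass
class PermutationResult:
    metric: str
    observed: float
    null: np.ndarray
    critical_value: float
    p_value: float
    n_perm: int
    alternative: str
    seed: int | None = None

    @property
    def reject(self) -> bool:
        """Rejection at the 95th-percentile criterion (nominal 0.05)."""
        if self.alternative == "less":
            return self.observed < self.critical_value
        return self.observed > self.critical_value


def _null_diffs_sampled(pooled, n_a, n_perm, rng):
    n = pooled.size
    total = pooled.sum()
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(n)[:n_a]
        sa = pooled[idx].sum()
        null[b] = sa / n_a - (total - sa) / (n - n_a)
    return null


def _null_diffs_exhaustive(pooled, n_a):
    n = pooled.size
    total = pooled.sum()
    out = []
    for idx in combinations(range(n), n_a):
        sa = pooled[list(idx)].sum()
        out.append(sa / n_a - (total - sa) / (n - n_a))
    return np.array(out)


def permutation_test(
    values_a,
    values_b,
    n_perm: int = 10000,
    alternative: str = "auto",
    seed: int | None = None,
    exhaustive: bool = False,
    metric: str = "",
) -> PermutationResult:
    """One-tailed randomised-reallocation test of mean(a) - mean(b).

    Parameters
    ----------
    alternative
        ``"greater"`` tests mean(a) > mean(b), ``"less"`` the reverse;
        ``"auto"`` runs the direction matching the observed sign (the
        result records which direction was taken).
    exhaustive
        Enumerate every label split instead of sampling; the p-value is
        then exact, #{null >= observed} / #splits, with no +1 correction.

    Notes
    -----
    The critical value is the 95th percentile of the null (5th for
    ``"less"``); ``result.reject`` applies it. With all values identical
    the test is degenerate: p = 1 is returned with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(a.mean() - b.mean())
    if alternative == "auto":
        alternative = "less" if observed < 0 else "greater"
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        warnings.warn("all values identical; permutation test degenerate (p = 1)",
                      stacklevel=2)
        null = np.zeros(n_perm)
        return PermutationResult(metric, observed, null, 0.0, 1.0, n_perm,
                                 alternative, seed)

    # ties are counted with a tiny tolerance so the identity relabelling
    # always matches the observed difference despite float round-off
    tol = 1e-12 * max(1.0, abs(observed))
    if exhaustive:
        null = _null_diffs_exhaustive(pooled, a.size)
        if alternative == "greater":
            p = float((null >= observed - tol).mean())
        else:
            p = float((null <= observed + tol).mean())
        n_eff = null.size
    else:
        rng = np.random.default_rng(seed)
        null = _null_diffs_sampled(pooled, a.size, n_perm, rng)
        if alternative == "greater":
            p = (int((null >= observed - tol).sum()) + 1) / (n_perm + 1)
        else:
            p = (int((null <= observed + tol).sum()) + 1) / (n_perm + 1)
        n_eff = n_perm
    q = 95.0 if alternative == "greater" else 5.0
    critical = float(np.percentile(null, q))
    return PermutationResult(metric, observed, null, critical, float(p),
                             n_eff, alternative, seed)


def permutation_test_many(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10000,
    alternative: str = "auto",
    seed: int | None = None,
) -> pd.DataFrame:
    """Vectorised permutation tests over many metrics at once.

    ``values_a`` is (n_a, m) and ``values_b`` (n_b, m); one shared
    sequence of label permutations is used for all m columns. Returns a
    frame with observed difference, directional p, critical value and
    rejection flag per column.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the metric dimension")
    n_a, m = a.shape
    pooled = np.vstack([a, b])
    n = pooled.shape[0]
    observed = a.mean(axis=0) - b.mean(axis=0)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, m))
    total = pooled.sum(axis=0)
    for bidx in range(n_perm):
        idx = rng.permutation(n)[:n_a]
        sa = pooled[idx].sum(axis=0)
        null[bidx] = sa / n_a - (total - sa) / (n - n_a)

    if alternative == "auto":
        signs = np.where(observed < 0, -1.0, 1.0)
    elif alternative == "greater":
        signs = np.ones(m)
    elif alternative == "less":
        signs = -np.ones(m)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    directed_null = null * signs
    directed_obs = observed * signs
    tol = 1e-12 * np.maximum(1.0, np.abs(directed_obs))
    p = ((directed_null >= directed_obs - tol).sum(axis=0) + 1) / (n_perm + 1)
    critical = np.percentile(directed_null, 95.0, axis=0)
    return pd.DataFrame({
        "observed_diff": observed,
        "p_value": p,
        "critical_value": critical * signs,
        "reject": directed_obs > critical,
        "direction": np.where(signs > 0, "greater", "less"),
    })


# --------------------------------------------------------------------------
# edge-wise statistics and NBS

def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def edge_t_matrix(fc_a: np.ndarray, fc_b: np.ndarray, fisher_z: bool = True) -> np.ndarray:
    """Pooled-variance two-sample t per edge (group a minus group b).

    Inputs are stacks of per-subject connectivity matrices,
    (n_subjects, n, n). Correlations are Fisher z-transformed first by
    default (variance stabilisation). Edges with zero pooled variance get
    t = 0 with a warning. Output is symmetric with zero diagonal.
    """
    fc_a = np.asarray(fc_a, dtype=float)
    fc_b = np.asarray(fc_b, dtype=float)
    if fc_a.ndim != 3 or fc_b.ndim != 3 or fc_a.shape[1:] != fc_b.shape[1:]:
        raise ValueError("inputs must be (n_subjects, n, n) with matching n")
    n_a, n_b = fc_a.shape[0], fc_b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 subjects per group")
    if fisher_z:
        fc_a, fc_b = _fisher_z(fc_a), _fisher_z(fc_b)
    ma, mb = fc_a.mean(axis=0), fc_b.mean(axis=0)
    va, vb = fc_a.var(axis=0, ddof=1), fc_b.var(axis=0, ddof=1)
    sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    dead = se == 0.0
    if dead[np.triu_indices_from(dead, k=1)].any():
        warnings.warn("zero pooled variance on some edges; their t set to 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(dead, 0.0, (ma - mb) / np.where(dead, 1.0, se))
    t = 0.5 * (t + t.T)
    np.fill_diagonal(t, 0.0)
    return t


@dataclass
class NbsComponent:
    nodes: tuple
    edges: tuple          # (i, j) with i < j, 0-based
    size_edges: int
    p_value: float | None = None


@dataclass
class NbsResult:
    t_matrix: np.ndarray
    threshold: float
    components: list
    null_max_size: np.ndarray
    n_perm: int
    seed: int | None
    two_sided: bool

    @property
    def significant(self) -> list:
        return [c for c in self.components if c.p_value is not None and c.p_value < 0.05]


def _suprathreshold_components(t, threshold, two_sided, node_mask=None):
    """Connected components of the suprathreshold edge mask; edge lists per component."""
    n = t.shape[0]
    stat = np.abs(t) if two_sided else t
    mask = np.triu(stat >= threshold, k=1)
    if node_mask is not None:
        keep = np.zeros(n, dtype=bool)
        keep[np.asarray(node_mask)] = True
        mask &= np.outer(keep, keep)
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        return [], ii, jj, np.array([])
    adj = coo_matrix((np.ones(ii.size), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    comps = []
    for lab in np.unique(labels[ii]):
        sel = labels[ii] == lab
        edges = tuple(zip(ii[sel].tolist(), jj[sel].tolist()))
        nodes = tuple(sorted({int(v) for v in ii[sel]} | {int(v) for v in jj[sel]}))
        comps.append(NbsComponent(nodes=nodes, edges=edges, size_edges=int(sel.sum())))
    comps.sort(key=lambda c: -c.size_edges)
    return comps, ii, jj, labels


def _max_component_size(ii, jj, n):
    """Largest component size in edges of the graph given by edge arrays."""
    if ii.size == 0:
        return 0
    adj = coo_matrix((np.ones(ii.size), (ii, jj)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return int(np.bincount(labels[ii]).max())


def nbs(
    fc_a: np.ndarray,
    fc_b: np.ndarray,
    threshold: float = 2.441,
    n_perm: int = 10000,
    seed: int | None = None,
    two_sided: bool = True,
    fisher_z: bool = True,
    node_mask=None,
) -> NbsResult:
    """Network-based statistic for a two-group connectivity comparison.

    Parameters
    ----------
    fc_a, fc_b
        Per-subject connectivity stacks, (n_subjects, n, n).
    threshold
        Primary t threshold T; edges with |t| >= T (or t >= T if
        ``two_sided=False``) enter the component search.
    node_mask
        Optional iterable of node indices restricting the analysis to the
        induced subnetwork (e.g. regions pre-selected by nodal findings);
        default is the whole network.

    Notes
    -----
    Component "size" is its edge count. The null distribution is the
    maximum component size under random reallocation of subjects to
    groups; each observed component's p-value is
    (#{null max >= size} + 1) / (n_perm + 1).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = edge_t_matrix(fc_a, fc_b, fisher_z=fisher_z)
    n = t.shape[0]
    comps, *_ = _suprathreshold_components(t, threshold, two_sided, node_mask)

    rng = np.random.default_rng(seed)
    n_a = fc_a.shape[0]
    stack = np.concatenate([fc_a, fc_b], axis=0)
    iu = np.triu_indices(n, k=1)
    z = _fisher_z(stack[:, iu[0], iu[1]]) if fisher_z else stack[:, iu[0], iu[1]]

    null_max = np.zeros(n_perm, dtype=int)
    keep = None
    if node_mask is not None:
        keepv = np.zeros(n, dtype=bool)
        keepv[np.asarray(node_mask)] = True
        keep = keepv[iu[0]] & keepv[iu[1]]
    n_tot = stack.shape[0]
    for b in range(n_perm):
        idx = rng.permutation(n_tot)
        za, zb = z[idx[:n_a]], z[idx[n_a:]]
        ma, mb = za.mean(axis=0), zb.mean(axis=0)
        va, vb = za.var(axis=0, ddof=1), zb.var(axis=0, ddof=1)
        sp2 = ((n_a - 1) * va + (n_tot - n_a - 1) * vb) / (n_tot - 2)
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / (n_tot - n_a)))
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = np.where(se == 0.0, 0.0, (ma - mb) / np.where(se == 0.0, 1.0, se))
        sv = np.abs(tv) if two_sided else tv
        sel = sv >= threshold
        if keep is not None:
            sel &= keep
        null_max[b] = _max_component_size(iu[0][sel], iu[1][sel], n)

    for c in comps:
        c.p_value = (int((null_max >= c.size_edges).sum()) + 1) / (n_perm + 1)
    return NbsResult(t_matrix=t, threshold=threshold, components=comps,
                     null_max_size=null_max, n_perm=n_perm, seed=seed,
                     two_sided=two_sided)


def component_summary(edges) -> tuple:
    """(node count, edge count, connected-component count) of an edge list.

    Duplicate (or reversed-duplicate) edges are collapsed with a warning.
    An empty list gives (0, 0, 0).
    """
    canon = [tuple(sorted(map(int, e))) for e in edges]
    uniq = sorted(set(canon))
    if len(uniq) < len(canon):
        warnings.warn(f"collapsed {len(canon) - len(uniq)} duplicate edge(s)",
                      stacklevel=2)
    if not uniq:
        return 0, 0, 0
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    nodes = sorted({v for e in uniq for v in e})
    for v in nodes:
        parent[v] = v
    for i, j in uniq:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = {find(v) for v in nodes}
    return len(nodes), len(uniq), len(roots)


# --------------------------------------------------------------------------
# distance classification

@dataclass(frozen=True)
class EdgeFinding:
    """One significant connection: endpoints, effect, length, length class."""

    region_a: int
    region_b: int
    fc_difference: float
    distance_mm: float
    long_range: bool


def edge_distance_classify(
    edges,
    centroids: pd.DataFrame,
    cutoff_mm: float = 75.0,
    fc_differences=None,
) -> list:
    """Classify connections as long-range (> cutoff, strict) or short.

    ``centroids`` must carry columns ``region_id``, ``x``, ``y``, ``z``
    (MNI millimetres). A connection is long-range iff the Euclidean
    distance between its endpoint centroids strictly exceeds the cutoff
    (exactly the cutoff counts as short).
    """
    coords = {}
    for _, row in centroids.iterrows():
        coords[int(row["region_id"])] = np.array([row["x"], row["y"], row["z"]], dtype=float)
    if fc_differences is None:
        fc_differences = [np.nan] * len(edges)
    out = []
    for (i, j), dfc in zip(edges, fc_differences):
        i, j = int(i), int(j)
        for r in (i, j):
            if r not in coords:
                raise KeyError(f"region {r} missing from centroid table")
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        out.append(EdgeFinding(region_a=i, region_b=j, fc_difference=float(dfc),
                               distance_mm=dist, long_range=dist > cutoff_mm))
    return out


# --------------------------------------------------------------------------
# metric-cognition regression

@dataclass
class RegressionResult:
    response: str
    predictor: str
    confounders: tuple
    coefficients: dict
    metric_coefficient: float
    metric_p_value: float
    r_squared: float
    adjusted_r_squared: float
    overall_p: float
    n: int


def metric_behavior_regression(
    table: pd.DataFrame,
    metric: str,
    score: str,
    confounders=("age", "sex", "education"),
) -> RegressionResult:
    """OLS of a cognitive score on a network metric plus confounders.

    Mirrors the standard confounder-adjusted association analysis: score ~
    intercept + metric + age + sex + education; reports the metric
    coefficient with its p-value, R-squared and adjusted R-squared
    (1 - (1 - R^2)(n-1)/(n-p-1)). Warns when residual degrees of freedom
    fall below 8, where such fits are fragile.
    """
    cols = [score, metric, *confounders]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns missing from table: {missing}")
    sub = table[cols].astype(float)
    if sub.isna().any().any():
        raise ValueError("missing values in regression columns")
    n = len(sub)
    x = sm.add_constant(sub[[metric, *confounders]])
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        raise ValueError(
            f"design matrix rank deficient (rank {rank} < {x.shape[1]}); "
            f"check collinearity among {[metric, *confounders]}"
        )
    if n <= x.shape[1]:
        raise ValueError(f"n = {n} too small for {x.shape[1]} parameters")
    fit = sm.OLS(sub[score], x).fit()
    if fit.df_resid < 8:
        warnings.warn(
            f"residual df = {fit.df_resid:.0f} < 8; estimates are fragile",
            stacklevel=2,
        )
    return RegressionResult(
        response=score,
        predictor=metric,
        confounders=tuple(confounders),
        coefficients=dict(fit.params),
        metric_coefficient=float(fit.params[metric]),
        metric_p_value=float(fit.pvalues[metric]),
        r_squared=float(fit.rsquared),
        adjusted_r_squared=float(fit.rsquared_adj),
        overall_p=float(fit.f_pvalue),
        n=n,
    )
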