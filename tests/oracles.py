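"""Brute-force reference implementations used only as test oracles.

Deliberately naive (O(n^3) loops, exhaustive enumeration, matrix powers)
and independent of the package's code paths.
"""
from itertools import combinations

import numpy as np


def floyd_warshall(a):
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_by_triangle_enumeration(a):
    n = a.shape[0]
    c = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if a[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(1 for u, w in combinations(nbrs, 2) if a[u, w])
        c[v] = 2.0 * tri / (k * (k - 1))
    return c


def path_length_reachable(d):
    n = d.shape[0]
    vals = [d[i, j] for i, j in combinations(range(n), 2) if np.isfinite(d[i, j])]
    return float(np.mean(vals))


def global_efficiency_pairsum(d):
    n = d.shape[0]
    total = sum(1.0 / d[i, j] for i, j in combinations(range(n), 2)
                if np.isfinite(d[i, j]) and d[i, j] > 0)
    return total / (n * (n - 1) / 2)


def local_efficiency_bruteforce(a):
    n = a.shape[0]
    total = 0.0
    for v in range(n):
        nbrs = [u for u in range(n) if a[v, u]]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += global_efficiency_pairsum(floyd_warshall(sub))
    return total / n


def nodal_efficiency_pairsum(d):
    n = d.shape[0]
    e = np.zeros(n)
    for i in range(n):
        e[i] = sum(1.0 / d[i, j] for j in range(n)
                   if j != i and np.isfinite(d[i, j]) and d[i, j] > 0) / (n - 1)
    return e


def betweenness_by_path_counts(a):
    """Normalised betweenness via shortest-path counts from matrix powers.

    The number of shortest s-t paths equals (A^d)[s, t] with d = d_st,
    since no shorter walks exist; the count through v factorises as
    (A^{d_sv})[s, v] * (A^{d_vt})[v, t] when d_sv + d_vt = d_st.
    """
    n = a.shape[0]
    d = floyd_warshall(a)
    maxd = int(np.nanmax(np.where(np.isfinite(d), d, 0)))
    powers = [np.eye(n, dtype=np.int64)]
    ai = a.astype(np.int64)
    for _ in range(maxd):
        powers.append(powers[-1] @ ai)
    b = np.zeros(n)
    for s, t in combinations(range(n), 2):
        if not np.isfinite(d[s, t]) or d[s, t] == 0:
            continue
        dst = int(d[s, t])
        sigma_st = powers[dst][s, t]
        for v in range(n):
            if v in (s, t) or not np.isfinite(d[s, v]) or not np.isfinite(d[v, t]):
                continue
            if d[s, v] + d[v, t] == d[s, t]:
                b[v] += powers[int(d[s, v])][s, v] * powers[int(d[v, t])][v, t] / sigma_st
    norm = (n - 1) * (n - 2) / 2.0
    return b / norm


def exhaustive_perm_pvalue(a, b, alternative="greater"):
    """Closed-form one-tailed permutation p via enumeration of label splits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    obs = a.mean() - b.mean()
    n, na = pooled.size, a.size
    tol = 1e-12 * max(1.0, abs(obs))
    hits = total = 0
    for idx in combinations(range(n), na):
        idx = list(idx)
        rest = [i for i in range(n) if i not in idx]
        diff = pooled[idx].mean() - pooled[rest].mean()
        total += 1
        if (alternative == "greater" and diff >= obs - tol) or \
           (alternative == "less" and diff <= obs + tol):
            hits += 1
    return hits / total


def connected_edge_components(edges):
    """Union-find over an edge list; returns list of frozensets of nodes."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups = {}
    for i, j in edges:
        groups.setdefault(find(i), set()).update((i, j))
    return [frozenset(g) for g in groups.values()]
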