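"""Independent brute-force oracles used to validate the graph metrics.

Everything here is deliberately naive — triple-loop Floyd–Warshall,
exhaustive path enumeration, exhaustive set-partition search — and shares no
code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = float("inf")


def random_adjacency(n: int, p: float, rng) -> np.ndarray:
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                a[i, j] = a[j, i] = 1
    return a


def bf_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if a[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if a[v, u]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(1 for x, y_ in itertools.combinations(nb, 2) if a[x, y_])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def bf_path_metrics(a: np.ndarray):
    """(nodal shortest path, nodal efficiency, Lp, Eglobal) by definition."""
    n = a.shape[0]
    d = bf_distances(a)
    nodal_sp = np.zeros(n)
    nodal_eff = np.zeros(n)
    lp_vals = []
    inv_vals = []
    for v in range(n):
        ds = [d[v, u] for u in range(n) if u != v and d[v, u] < INF]
        nodal_sp[v] = sum(ds) / len(ds) if ds else 0.0
        nodal_eff[v] = sum(1.0 / d[v, u] for u in range(n) if u != v and d[v, u] < INF) / (n - 1)
        for u in range(n):
            if u == v:
                continue
            if d[v, u] < INF:
                lp_vals.append(d[v, u])
                inv_vals.append(1.0 / d[v, u])
            else:
                inv_vals.append(0.0)
    lp = sum(lp_vals) / len(lp_vals) if lp_vals else float("nan")
    eglob = sum(inv_vals) / (n * (n - 1))
    return nodal_sp, nodal_eff, lp, eglob


def _all_shortest_paths(a, s, t, d):
    """Every shortest s-t path, by DFS constrained to descend the distance."""
    if d[s, t] == INF:
        return []
    paths = []

    def extend(path):
        cur = path[-1]
        if cur == t:
            paths.append(path)
            return
        for u in range(a.shape[0]):
            if a[cur, u] and d[u, t] == d[cur, t] - 1:
                extend(path + [u])

    extend([s])
    return paths


def bf_betweenness(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = bf_distances(a)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(a, s, t, d)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


def bf_local_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if a[v, u]]
        if len(nb) < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        _, _, _, eglob = bf_path_metrics(sub)
        out[v] = eglob
    return out


def bf_modularity(a: np.ndarray, blocks) -> float:
    """Q = sum_i [l_i/L - (d_i/2L)^2] evaluated straight from the partition."""
    total = a.sum() / 2.0
    q = 0.0
    for block in blocks:
        block = list(block)
        l_i = a[np.ix_(block, block)].sum() / 2.0
        d_i = a[block, :].sum()
        q += l_i / total - (d_i / (2 * total)) ** 2
    return q


def set_partitions(items):
    """All partitions of a list (restricted-growth-string enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def bf_max_modularity(a: np.ndarray) -> float:
    best = -INF
    for part in set_partitions(range(a.shape[0])):
        best = max(best, bf_modularity(a, part))
    return best


def bf_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook formula: sum of products of deviations over root sum squares."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den
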