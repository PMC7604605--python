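"""Independent brute-force oracles for the weighted graph metrics.

Everything here is deliberately naive: Floyd-Warshall triple loops,
exhaustive simple-path enumeration, explicit subgraph reconstruction.
These never share code with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np

REL_TIE_TOL = 1e-12


def oracle_distances(w: np.ndarray) -> np.ndarray:
    """Floyd-Warshall on lengths 1/w."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_strength(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    return np.array([sum(w[i, j] for j in range(n)) for i in range(n)])


def oracle_nodal_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    if n < 2:
        return np.zeros(n)
    d = oracle_distances(w)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
        out[i] = acc / (n - 1)
    return out


def oracle_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    return float(oracle_nodal_efficiency(w).mean()) if n else 0.0


def oracle_clustering(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    wmax = w.max() if w.size else 0.0
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                acc += ((w[i, j] / wmax) * (w[i, h] / wmax)
                        * (w[j, h] / wmax)) ** (1.0 / 3.0)
        out[i] = acc / (k * (k - 1))
    return out


def _all_simple_paths(w, src, dst):
    n = w.shape[0]
    stack = [(src, [src], 0.0)]
    while stack:
        node, path, length = stack.pop()
        if node == dst:
            yield path, length
            continue
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in path:
                stack.append((nxt, path + [nxt], length + 1.0 / w[node, nxt]))


def oracle_betweenness(w: np.ndarray) -> np.ndarray:
    """Exhaustive enumeration of shortest simple paths per pair."""
    n = w.shape[0]
    b = np.zeros(n)
    if n < 3:
        return b
    for j, h in itertools.combinations(range(n), 2):
        paths = list(_all_simple_paths(w, j, h))
        if not paths:
            continue
        best = min(length for _, length in paths)
        tol = best * REL_TIE_TOL + 1e-300
        shortest = [p for p, length in paths if length <= best + tol]
        sigma = len(shortest)
        for i in range(n):
            if i in (j, h):
                continue
            through = sum(1 for p in shortest if i in p)
            b[i] += 2.0 * through / sigma   # ordered pairs: (j,h) and (h,j)
    return b / ((n - 1) * (n - 2))


def oracle_vulnerability(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    eg = oracle_global_efficiency(w)
    out = np.zeros(n)
    for i in range(n):
        keep = [k for k in range(n) if k != i]
        sub = w[np.ix_(keep, keep)]
        out[i] = (eg - oracle_global_efficiency(sub)) / eg
    return out


def oracle_local_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        total += oracle_global_efficiency(w[np.ix_(nbrs, nbrs)])
    return total / n


def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 0.45) -> np.ndarray:
    """Random symmetric nonnegative matrix with continuous weights."""
    w = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < density:
            w[i, j] = w[j, i] = rng.uniform(0.2, 3.0)
    return w
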