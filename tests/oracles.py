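"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive enumeration, textbook
recursions, O(n^3) loops — and shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# -- partitions / modularity -------------------------------------------------

def set_partitions(n: int):
    """All partitions of range(n) as affiliation vectors (restricted growth)."""
    def grow(prefix, k):
        i = len(prefix)
        if i == n:
            yield list(prefix)
            return
        for label in range(k + 1):
            yield from grow(prefix + [label], max(k, label + 1))
    yield from grow([], 0)


def partition_q(W: np.ndarray, aff) -> float:
    """Weighted Newman Q of a partition, written as the direct double sum."""
    W = np.asarray(W, dtype=float)
    total2 = W.sum()
    s = W.sum(axis=1)
    q = 0.0
    n = W.shape[0]
    for i in range(n):
        for j in range(n):
            if aff[i] == aff[j]:
                q += W[i, j] - s[i] * s[j] / total2
    return q / total2


def brute_force_max_modularity(W: np.ndarray) -> float:
    return max(partition_q(W, aff) for aff in set_partitions(W.shape[0]))


# -- connectivity / distances ------------------------------------------------

def union_find_n_components(n: int, edges) -> int:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return len({find(i) for i in range(n)})


def bfs_hop_distances(A: np.ndarray) -> np.ndarray:
    """All-pairs hop counts by breadth-first search."""
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    for src in range(n):
        D[src, src] = 0
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in np.flatnonzero(A[u]):
                if np.isinf(D[src, v]):
                    D[src, v] = D[src, u] + 1
                    queue.append(v)
    return D


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    D = np.array(lengths, dtype=float)
    n = D.shape[0]
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


# -- clustering ----------------------------------------------------------------

def brute_force_clustering(A: np.ndarray) -> float:
    """Mean binary clustering coefficient by explicit triangle counting."""
    n = A.shape[0]
    cs = []
    for i in range(n):
        neigh = np.flatnonzero(A[i])
        k = len(neigh)
        if k < 2:
            cs.append(0.0)
            continue
        t = sum(1 for a, b in itertools.combinations(neigh, 2) if A[a, b])
        cs.append(2.0 * t / (k * (k - 1)))
    return float(np.mean(cs))


# -- betweenness ---------------------------------------------------------------

def _all_simple_paths(adj: dict, src: int, dst: int):
    stack = [(src, [src])]
    while stack:
        node, path = stack.pop()
        if node == dst:
            yield path
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))


def brute_force_betweenness(lengths: np.ndarray) -> np.ndarray:
    """Normalized betweenness by enumerating all simple paths.

    Use integer edge lengths so equal-length ties are exact.
    """
    n = lengths.shape[0]
    adj = {i: [j for j in range(n)
               if j != i and np.isfinite(lengths[i, j])] for i in range(n)}
    b = np.zeros(n)
    for h in range(n):
        for j in range(h + 1, n):
            paths = list(_all_simple_paths(adj, h, j))
            if not paths:
                continue
            costs = [sum(lengths[u, v] for u, v in zip(p, p[1:]))
                     for p in paths]
            best = min(costs)
            shortest = [p for p, c in zip(paths, costs) if c == best]
            rho = len(shortest)
            for i in range(n):
                if i in (h, j):
                    continue
                rho_i = sum(1 for p in shortest if i in p)
                b[i] += rho_i / rho
    # unordered pair sum doubled = ordered-pair sum; normalize by (n-1)(n-2)
    return 2.0 * b / ((n - 1) * (n - 2))


# -- statistics ------------------------------------------------------------------

def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def percentile_linear(sorted_vals: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile computed from the order statistics."""
    vals = np.sort(np.asarray(sorted_vals, dtype=float))
    h = (len(vals) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(vals) - 1)
    return vals[lo] + (h - lo) * (vals[hi] - vals[lo])
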