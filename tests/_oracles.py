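"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's union-find machinery: minimax path
distances come from exhaustive simple-path enumeration, component counts
from scratch graph rebuilds at every threshold.
"""

from __future__ import annotations

import numpy as np


def bipartite_adjacency(D: np.ndarray) -> dict:
    """Adjacency with edge weights for a bipartite distance matrix; rows are
    nodes 0..n1-1, columns n1..n1+n2-1; entries of exactly 1 are non-edges."""
    n1, n2 = D.shape
    adj: dict[int, list[tuple[int, float]]] = {u: [] for u in range(n1 + n2)}
    for i in range(n1):
        for j in range(n2):
            w = D[i, j]
            if w < 1.0:
                adj[i].append((n1 + j, w))
                adj[n1 + j].append((i, w))
    return adj


def symmetric_adjacency(D: np.ndarray) -> dict:
    p = D.shape[0]
    adj: dict[int, list[tuple[int, float]]] = {u: [] for u in range(p)}
    for i in range(p):
        for j in range(i + 1, p):
            w = D[i, j]
            if w < 1.0:
                adj[i].append((j, w))
                adj[j].append((i, w))
    return adj


def minimax_all_simple_paths(adj: dict, source: int, target: int) -> float:
    """min over all simple paths of the maximum edge weight; 1.0 if no path."""
    best = [1.0]
    visited = [False] * len(adj)

    def dfs(u: int, bottleneck: float) -> None:
        if u == target:
            best[0] = min(best[0], bottleneck)
            return
        visited[u] = True
        for v, w in adj[u]:
            if not visited[v]:
                nb = max(bottleneck, w)
                if nb < best[0]:  # exact: a worse prefix can never win
                    dfs(v, nb)
        visited[u] = False

    dfs(source, 0.0)
    return best[0]


def components_at(adj: dict, eps: float) -> list[set]:
    """Connected components of the graph with edges of weight <= eps,
    found by scratch breadth-first search."""
    n = len(adj)
    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        comp = {s}
        seen[s] = True
        frontier = [s]
        while frontier:
            u = frontier.pop()
            for v, w in adj[u]:
                if w <= eps and not seen[v]:
                    seen[v] = True
                    comp.add(v)
                    frontier.append(v)
        comps.append(comp)
    return comps


def betti_recount(adj: dict, eps: float, partition_nodes: set) -> int:
    """Number of components containing at least one node of the partition."""
    return sum(1 for c in components_at(adj, eps) if c & partition_nodes)


def random_bipartite_distance(rng: np.random.Generator, p: int,
                              density: float = 0.6) -> np.ndarray:
    """Random distances in [0, 1) with the remainder set to the non-edge 1."""
    D = rng.random((p, p)) * 0.999
    D[rng.random((p, p)) > density] = 1.0
    return D
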