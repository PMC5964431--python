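"""Independent brute-force oracles for graph metrics and BH-FDR.

Everything here is deliberately naive pure Python (exhaustive triangle
counts, hand-rolled BFS, recursive shortest-path enumeration, the literal
step-up definition of Benjamini-Hochberg) so the production implementations
are checked against a fully independent route.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_distances(A: np.ndarray) -> list[list[float]]:
    """All-pairs shortest-path lengths by per-source BFS; inf if unreachable."""
    n = A.shape[0]
    out = []
    for s in range(n):
        dist = [float("inf")] * n
        dist[s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if A[u][v] and dist[v] == float("inf"):
                    dist[v] = dist[u] + 1
                    q.append(v)
        out.append(dist)
    return out


def brute_clustering(A: np.ndarray) -> tuple[list[float], float]:
    """Per-node clustering by exhaustive neighbour-pair counting."""
    n = A.shape[0]
    c_node = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i][j]]
        k = len(nbrs)
        if k < 2:
            c_node.append(0.0)
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if A[nbrs[a]][nbrs[b]]
        )
        c_node.append(2.0 * links / (k * (k - 1)))
    return c_node, sum(c_node) / n


def brute_global_efficiency(A: np.ndarray) -> float:
    n = A.shape[0]
    D = brute_distances(A)
    total = sum(
        1.0 / D[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and D[i][j] != float("inf")
    )
    return total / (n * (n - 1))


def brute_char_path_length(A: np.ndarray) -> float:
    e = brute_global_efficiency(A)
    return float("inf") if e == 0 else 1.0 / e


def brute_local_efficiency(A: np.ndarray) -> float:
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if A[i][j]]
        m = len(nbrs)
        if m < 2:
            continue
        sub = np.array([[A[a][b] for b in nbrs] for a in nbrs])
        total += brute_global_efficiency(sub) * 1.0  # mean reciprocal distance
    return total / n


def _all_shortest_paths(A: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Enumerate every shortest s-t path via BFS layers + recursive backtrack."""
    n = A.shape[0]
    dist = brute_distances(A)[s]
    if dist[t] == float("inf"):
        return []
    paths: list[list[int]] = []

    def extend(path: list[int]) -> None:
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if A[u][v] and dist[v] == dist[u] + 1:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_betweenness(A: np.ndarray) -> list[float]:
    """B_i over unordered source-target pairs, endpoints excluded."""
    n = A.shape[0]
    B = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(A, s, t)
            if not paths:
                continue
            n_paths = len(paths)
            for path in paths:
                for node in path[1:-1]:
                    B[node] += 1.0 / n_paths
    return B


def brute_bh_reject(p_values: np.ndarray, q: float) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: largest k with p_(k) <= k q / m."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    if k_star:
        threshold = p[order[k_star - 1]]
        reject = p <= threshold
    return reject


def random_graph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi-style symmetric 0/1 adjacency with zero diagonal."""
    A = (rng.random((n, n)) < density).astype(np.uint8)
    A = np.triu(A, 1)
    return A + A.T
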