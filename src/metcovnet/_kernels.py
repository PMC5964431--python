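"""Numba-compiled hot paths: edge swaps and BFS efficiency sums.

The permutation procedures evaluate graph metrics on hundreds of thousands
of 90-node networks, so the inner loops (degree-preserving double-edge
swaps, breadth-first shortest paths) are compiled.  All kernels operate on
dense uint8 adjacency matrices and are deterministic for a fixed seed
(numba's per-thread Mersenne Twister seeded via np.random.seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def double_edge_swap_kernel(
    A: np.ndarray, edges: np.ndarray, n_swap: int, seed: int, max_tries: int
) -> int:
    """Attempt accepted double-edge swaps; returns the number accepted.

    A swap picks edges (a,b), (c,d) with four distinct endpoints and replaces
    them with (a,d), (c,b) when neither exists, preserving every degree.
    Mutates ``A`` and ``edges`` in place.
    """
    np.random.seed(seed)
    n_edges = edges.shape[0]
    accepted = 0
    tries = 0
    while accepted < n_swap and tries < max_tries:
        tries += 1
        e1 = np.random.randint(0, n_edges)
        e2 = np.random.randint(0, n_edges)
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.random() < 0.5:
            tmp = c
            c = d
            d = tmp
        if a == c or a == d or b == c or b == d:
            continue
        if A[a, d] == 1 or A[c, b] == 1:
            continue
        A[a, b] = 0
        A[b, a] = 0
        A[c, d] = 0
        A[d, c] = 0
        A[a, d] = 1
        A[d, a] = 1
        A[c, b] = 1
        A[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        accepted += 1
    return accepted


@njit(cache=True)
def reciprocal_distance_sum(A: np.ndarray) -> float:
    """Sum of 1/d_ij over ordered pairs i != j (disconnected pairs add 0).

    Unweighted shortest paths by BFS from every source.
    """
    n = A.shape[0]
    total = 0.0
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    for s in range(n):
        for j in range(n):
            dist[j] = -1
        dist[s] = 0
        head = 0
        tail = 1
        queue[0] = s
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for v in range(n):
                if A[u, v] == 1 and dist[v] == -1:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for j in range(n):
            if j != s and dist[j] > 0:
                total += 1.0 / dist[j]
    return total


@njit(cache=True)
def local_efficiency_kernel(A: np.ndarray) -> float:
    """Mean over nodes of the efficiency of the neighbourhood-induced subgraph.

    Nodes with fewer than two neighbours contribute 0.
    """
    n = A.shape[0]
    total = 0.0
    nbrs = np.empty(n, np.int64)
    for i in range(n):
        m = 0
        for j in range(n):
            if A[i, j] == 1:
                nbrs[m] = j
                m += 1
        if m < 2:
            continue
        sub = np.empty((m, m), np.uint8)
        for a in range(m):
            for b in range(m):
                sub[a, b] = A[nbrs[a], nbrs[b]]
        total += reciprocal_distance_sum(sub) / (m * (m - 1))
    return total / n
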