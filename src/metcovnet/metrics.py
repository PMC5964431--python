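"""Binary-network topology metrics, null models, small-world indices, hubs.

Conventions, applied uniformly:

* Distances are unweighted shortest-path lengths; disconnected pairs
  contribute 0 to reciprocal sums (equivalently an infinite path length).
* The characteristic path length L is the reciprocal of the mean reciprocal
  distance (the harmonic definition), so L * E_glob = 1 whenever E_glob > 0.
* Nodes of degree < 2 contribute 0 to the mean clustering coefficient and to
  local efficiency.
* Betweenness counts unordered source-target pairs with the node excluded as
  an endpoint; the normalized value bi = B_i / mean(B) has mean 1 on any
  non-degenerate graph, and bi > 1.5 flags a hub.
* Null networks preserve the degree sequence exactly (double-edge swaps);
  gamma = C / C_rand, lambda = L / L_rand, sigma = gamma / lambda, with the
  null means taken over ``n_null`` rewired networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import igraph as ig
import numpy as np
import pandas as pd

from ._kernels import (
    double_edge_swap_kernel,
    local_efficiency_kernel,
    reciprocal_distance_sum,
)
from .exceptions import NumericalError, ParameterError

DEFAULT_N_NULL = 200
DEFAULT_SWAPS_PER_EDGE = 10
HUB_THRESHOLD = 1.5


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ParameterError("adjacency must be a square matrix")
    if not np.array_equal(A, A.T):
        raise ParameterError("adjacency must be symmetric")
    if np.diag(A).any():
        raise ParameterError("adjacency must have a zero diagonal")
    return A.astype(np.uint8)


def clustering_coefficient(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node and mean clustering coefficient.

    C_i = 2 E(i) / (k_i (k_i - 1)) where E(i) counts edges among i's
    neighbours; nodes with degree < 2 contribute C_i = 0.
    """
    A = _check_adjacency(A)
    Af = A.astype(float)
    k = Af.sum(axis=1)
    triangles = np.diag(Af @ Af @ Af) / 2.0
    denom = k * (k - 1)
    c_node = np.divide(2.0 * triangles, denom, out=np.zeros_like(denom), where=denom > 0)
    return c_node, float(c_node.mean())


def global_efficiency(A: np.ndarray) -> float:
    """Mean reciprocal shortest-path length over ordered pairs."""
    A = _check_adjacency(A)
    n = A.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 nodes")
    return float(reciprocal_distance_sum(A) / (n * (n - 1)))


def characteristic_path_length(A: np.ndarray) -> float:
    """Harmonic characteristic path length L = 1 / E_glob (inf if edgeless)."""
    e = global_efficiency(A)
    return float("inf") if e == 0 else 1.0 / e


def local_efficiency(A: np.ndarray) -> float:
    """Mean, over nodes, of the global efficiency of each neighbourhood subgraph.

    Distances are computed inside the subgraph induced by the node's
    neighbours; nodes with fewer than 2 neighbours contribute 0.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 nodes")
    return float(local_efficiency_kernel(A))


def betweenness_normalized(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Betweenness B_i and its network-mean-normalized form bi = B_i / mean(B).

    B_i sums, over unordered source-target pairs excluding i, the fraction of
    shortest paths passing through i.  On a graph where no shortest path has
    an interior node (e.g. complete graphs) bi is all-zero and flagged
    degenerate via a warning.
    """
    A = _check_adjacency(A)
    n = A.shape[0]
    if n < 3:
        raise ParameterError("betweenness needs at least 3 nodes")
    src, dst = np.nonzero(np.triu(A, 1))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())))
    B = np.asarray(g.betweenness(), dtype=float)
    mean_b = B.mean()
    if mean_b == 0:
        warnings.warn("all betweenness values are zero; bi is degenerate", UserWarning, stacklevel=2)
        return B, np.zeros_like(B)
    return B, B / mean_b


def rewire_null(
    A: np.ndarray, seed: int, swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
) -> np.ndarray:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``swaps_per_edge * |E|`` accepted swaps (up to 100x as many
    tries); warns and returns a partially/un-rewired copy when the graph is
    too constrained to swap.  Deterministic for a fixed seed.
    """
    A = _check_adjacency(A).copy()
    if swaps_per_edge < 0:
        raise ParameterError("swaps_per_edge must be nonnegative")
    src, dst = np.nonzero(np.triu(A, 1))
    n_edges = src.size
    if n_edges < 2:
        raise ParameterError("need at least 2 edges to rewire")
    if swaps_per_edge == 0:
        return A
    edges = np.column_stack([src, dst]).astype(np.int64)
    n_swap = swaps_per_edge * n_edges
    accepted = double_edge_swap_kernel(A, edges, n_swap, int(seed) & 0x7FFFFFFF, 100 * n_swap)
    if accepted < n_swap:
        warnings.warn(
            f"graph too constrained: {accepted}/{n_swap} swaps accepted",
            UserWarning,
            stacklevel=2,
        )
    return A


def _null_seeds(seed: int, n_null: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_null)


def small_world_indices(
    A: np.ndarray,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> tuple[float, float, float, float, float]:
    """(gamma, lambda, sigma, C_rand, L_rand) against degree-preserving nulls.

    Null networks with zero clustering or infinite path length are excluded
    from the null means (they carry no ratio); if all are degenerate a
    NumericalError is raised.
    """
    A = _check_adjacency(A)
    if A.sum() == 0:
        raise ParameterError("small-world indices need a non-edgeless graph")
    if n_null < 1:
        raise ParameterError("n_null must be at least 1")
    _, c_obs = clustering_coefficient(A)
    l_obs = characteristic_path_length(A)
    n = A.shape[0]
    src, dst = np.nonzero(np.triu(A, 1))
    base_edges = np.column_stack([src, dst]).astype(np.int64)
    n_swap = swaps_per_edge * base_edges.shape[0]
    c_null, l_null = [], []
    for s in _null_seeds(seed, n_null):
        null = A.copy()
        if n_swap > 0:
            double_edge_swap_kernel(
                null, base_edges.copy(), n_swap, int(s) & 0x7FFFFFFF, 100 * n_swap
            )
        nf = null.astype(float)
        k = nf.sum(axis=1)
        denom = k * (k - 1)
        tri = np.diag(nf @ nf @ nf)  # = 2 * triangle count per node
        c_r = float(
            np.divide(tri, denom, out=np.zeros_like(denom), where=denom > 0).mean()
        )
        e_r = reciprocal_distance_sum(null) / (n * (n - 1))
        if c_r > 0 and e_r > 0:
            c_null.append(c_r)
            l_null.append(1.0 / e_r)
    if not c_null:
        raise NumericalError("all null networks were degenerate")
    c_rand = float(np.mean(c_null))
    l_rand = float(np.mean(l_null))
    gamma = c_obs / c_rand
    lam = l_obs / l_rand
    return gamma, lam, gamma / lam, c_rand, l_rand


def detect_hubs(bi_node: np.ndarray, threshold: float = HUB_THRESHOLD) -> list[int]:
    """Indices with bi strictly above the hub threshold, sorted by descending bi."""
    bi = np.asarray(bi_node, dtype=float)
    if not bi.any():
        warnings.warn("degenerate bi vector (all zero); no hubs", UserWarning, stacklevel=2)
        return []
    idx = np.flatnonzero(bi > threshold)
    return idx[np.argsort(-bi[idx], kind="stable")].tolist()


@dataclass
class MetricSet:
    """All network parameters for one binarized group network."""

    C: float
    C_node: np.ndarray
    L: float
    E_glob: float
    E_loc: float
    gamma: float
    lam: float
    sigma: float
    C_rand: float
    L_rand: float
    B_node: np.ndarray
    bi_node: np.ndarray
    n_null: int
    seed: int

    def summary(self) -> dict[str, float]:
        return {
            "C": self.C,
            "L": self.L,
            "E_glob": self.E_glob,
            "E_loc": self.E_loc,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "C_rand": self.C_rand,
            "L_rand": self.L_rand,
        }

    def node_table(self, region_ids: list[int] | None = None) -> pd.DataFrame:
        n = len(self.B_node)
        ids = region_ids if region_ids is not None else list(range(1, n + 1))
        return pd.DataFrame(
            {"region_id": ids, "C": self.C_node, "B": self.B_node, "bi": self.bi_node}
        )

    def save_json(self, path: str | Path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def compute_metric_set(
    A: np.ndarray,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> MetricSet:
    """Evaluate every network parameter on one adjacency."""
    A = _check_adjacency(A)
    c_node, c = clustering_coefficient(A)
    e_glob = global_efficiency(A)
    L = float("inf") if e_glob == 0 else 1.0 / e_glob
    e_loc = local_efficiency(A)
    gamma, lam, sigma, c_rand, l_rand = small_world_indices(A, n_null, seed, swaps_per_edge)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        b_node, bi_node = betweenness_normalized(A)
    return MetricSet(
        C=c,
        C_node=c_node,
        L=L,
        E_glob=e_glob,
        E_loc=e_loc,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        C_rand=c_rand,
        L_rand=l_rand,
        B_node=b_node,
        bi_node=bi_node,
        n_null=n_null,
        seed=seed,
    )
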