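"""Nonparametric permutation inference for group network differences.

Subjects from the two cohorts are pooled, group labels are reshuffled
preserving the original group sizes, and the full partial-correlation ->
binarization -> graph-metric chain is recomputed under every relabeling.
P-values use the add-one convention p = (1 + #qualifying nulls) / (1 + n_perm)
so they are never zero; at the decision level this matches a 95th-percentile
cutoff on the null distribution.

The pooled rows are put into a canonical (lexicographic) order before
relabelings are drawn, so swapping the cohort argument order flips the sign
of every observed difference while leaving two-sided p-values unchanged for
equal group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InferenceError, NumericalError, ParameterError
from .metrics import (
    DEFAULT_SWAPS_PER_EDGE,
    HUB_THRESHOLD,
    betweenness_normalized,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    small_world_indices,
)
from .network import SPARSITY_GRID, binarize_matrix, partial_correlation
from .parcellation import RegionMatrix

CURVE_METRICS = ("C", "L", "E_glob", "E_loc", "gamma", "lambda", "sigma")
TAILS = ("greater", "less", "two_sided")


@dataclass
class NullDistribution:
    """Permutation null samples of a group-difference statistic."""

    statistic_name: str
    observed: float
    null_samples: np.ndarray
    n_perm: int
    p_value: float
    tail: str
    seed: int

    def __post_init__(self) -> None:
        self.null_samples = np.asarray(self.null_samples, dtype=float)
        if len(self.null_samples) != self.n_perm:
            raise ParameterError("null sample count must equal n_perm")
        if not 0 < self.p_value <= 1:
            raise ParameterError("add-one p-values lie in (0, 1]")
        if self.tail not in TAILS:
            raise ParameterError(f"tail must be one of {TAILS}")


def add_one_p(observed: float, null_samples: np.ndarray, tail: str) -> float:
    """p = (1 + #{qualifying nulls}) / (1 + n_perm); never 0, never > 1.

    NaN null samples (degenerate permutations) are excluded from both counts;
    a NaN observed value yields a NaN p.
    """
    null = np.asarray(null_samples, dtype=float)
    null = null[~np.isnan(null)]
    if np.isnan(observed) or len(null) == 0:
        return float("nan")
    if tail == "greater":
        count = int(np.sum(null >= observed))
    elif tail == "less":
        count = int(np.sum(null <= observed))
    elif tail == "two_sided":
        count = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ParameterError(f"tail must be one of {TAILS}")
    return (1 + count) / (1 + len(null))


def _canonical_pool(
    cohort_a: RegionMatrix, cohort_b: RegionMatrix
) -> tuple[np.ndarray, int, int]:
    if cohort_a.region_ids != cohort_b.region_ids:
        raise ParameterError("cohorts must share the same region set and order")
    pooled = np.vstack([cohort_a.values, cohort_b.values])
    # canonical row order: lexicographic over columns (first column primary)
    order = np.lexsort(pooled.T[::-1])
    return pooled[order], cohort_a.n_subjects, cohort_b.n_subjects


def permutation_test_statistic(
    cohort_a: RegionMatrix,
    cohort_b: RegionMatrix,
    statistic: Callable[[RegionMatrix, RegionMatrix], float],
    n_perm: int = 1000,
    tail: str = "greater",
    seed: int = 0,
    statistic_name: str = "statistic",
) -> NullDistribution:
    """Group-reassignment permutation test of a scalar group-difference statistic."""
    if n_perm < 100:
        raise ParameterError("n_perm must be at least 100")
    if tail not in TAILS:
        raise ParameterError(f"tail must be one of {TAILS}")
    observed = float(statistic(cohort_a, cohort_b))
    if not np.isfinite(observed):
        raise InferenceError(f"observed statistic is non-finite ({observed})")
    pooled, n_a, _ = _canonical_pool(cohort_a, cohort_b)
    region_ids = list(cohort_a.region_ids)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        pseudo_a = RegionMatrix(
            pooled[idx[:n_a]],
            [f"p{j}" for j in range(n_a)],
            region_ids,
            normalized=cohort_a.normalized,
        )
        pseudo_b = RegionMatrix(
            pooled[idx[n_a:]],
            [f"p{j}" for j in range(pooled.shape[0] - n_a)],
            region_ids,
            normalized=cohort_b.normalized,
        )
        nulls[i] = statistic(pseudo_a, pseudo_b)
    bad = ~np.isfinite(nulls)
    if bad.mean() > 0.10:
        raise InferenceError(
            f"statistic non-finite in {int(bad.sum())}/{n_perm} permutations "
            f"(first bad null index {int(np.flatnonzero(bad)[0])})"
        )
    return NullDistribution(
        statistic_name=statistic_name,
        observed=observed,
        null_samples=nulls,
        n_perm=n_perm,
        p_value=add_one_p(observed, nulls, tail),
        tail=tail,
        seed=seed,
    )


def make_network_statistic(
    metric: str,
    sparsity: float = 0.21,
    shrinkage: float = 0.5,
    n_null: int = 10,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> Callable[[RegionMatrix, RegionMatrix], float]:
    """Statistic factory: metric(group A network) - metric(group B network).

    ``n_null`` applies only to the small-world ratios (gamma/lambda/sigma),
    which need rewired nulls at every evaluation.
    """
    if metric not in CURVE_METRICS:
        raise ParameterError(f"metric must be one of {CURVE_METRICS}")
    needs_null = metric in ("gamma", "lambda", "sigma")

    def one_group(X: np.ndarray) -> float:
        A = binarize_matrix(partial_correlation(X, shrinkage), sparsity)
        if needs_null:
            gamma, lam, sigma, _, _ = small_world_indices(A, n_null, seed, swaps_per_edge)
            return {"gamma": gamma, "lambda": lam, "sigma": sigma}[metric]
        if metric == "C":
            return clustering_coefficient(A)[1]
        if metric == "E_glob":
            return global_efficiency(A)
        if metric == "E_loc":
            return local_efficiency(A)
        e = global_efficiency(A)  # L, harmonic definition
        return float("inf") if e == 0 else 1.0 / e

    def stat(a: RegionMatrix, b: RegionMatrix) -> float:
        return float(one_group(a.values) - one_group(b.values))

    return stat


def _fast_metrics(A: np.ndarray) -> tuple[float, float, float, float]:
    """(C, L, E_glob, E_loc) without null models."""
    _, c = clustering_coefficient(A)
    e_glob = global_efficiency(A)
    L = float("inf") if e_glob == 0 else 1.0 / e_glob
    e_loc = local_efficiency(A)
    return c, L, e_glob, e_loc


def _seven_metrics(
    X: np.ndarray,
    sparsity: float,
    shrinkage: float,
    n_null: int,
    seed: int,
    swaps_per_edge: int,
) -> np.ndarray:
    """Evaluate CURVE_METRICS for one cohort table at one sparsity.

    When every rewired null is degenerate (possible at very sparse thresholds
    with few nulls) the small-world ratios are reported as NaN rather than
    aborting the permutation loop.
    """
    A = binarize_matrix(partial_correlation(X, shrinkage), sparsity)
    c, L, e_glob, e_loc = _fast_metrics(A)
    try:
        gamma, lam, sigma, _, _ = small_world_indices(A, n_null, seed, swaps_per_edge)
    except NumericalError:
        gamma = lam = sigma = float("nan")
    return np.array([c, L, e_glob, e_loc, gamma, lam, sigma])


def metric_sparsity_curves(
    cohort_a: RegionMatrix,
    cohort_b: RegionMatrix,
    grid: Sequence[float] | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    shrinkage: float = 0.5,
    n_null: int = 200,
    n_null_perm: int = 10,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> pd.DataFrame:
    """Per-sparsity group values and permutation p for all seven curve metrics.

    One relabeling serves all metrics within a sparsity (the shuffles are
    shared).  Observed small-world ratios use ``n_null`` rewired nulls; the
    ratios recomputed inside the permutation loop use the lighter
    ``n_null_perm``.  P-values are one-tailed toward the observed direction;
    the tail used is reported per row.
    """
    grid_arr = SPARSITY_GRID if grid is None else np.asarray(grid, dtype=float)
    if ((grid_arr <= 0) | (grid_arr >= 1)).any():
        raise ParameterError("sparsity grid must lie within (0, 1)")
    pooled, n_a, _ = _canonical_pool(cohort_a, cohort_b)
    master = np.random.default_rng(seed)
    rows = []
    for s in grid_arr:
        s_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(s_seed)
        # one null seed shared by both groups (common random numbers): with
        # identical cohorts the small-world ratios then cancel exactly
        obs_seed = int(rng.integers(2**31 - 1))
        obs_a = _seven_metrics(cohort_a.values, s, shrinkage, n_null, obs_seed, swaps_per_edge)
        obs_b = _seven_metrics(cohort_b.values, s, shrinkage, n_null, obs_seed, swaps_per_edge)
        null_diffs = np.empty((n_perm, len(CURVE_METRICS)))
        for p in range(n_perm):
            idx = rng.permutation(pooled.shape[0])
            ns = int(rng.integers(2**31 - 1))
            ma = _seven_metrics(pooled[idx[:n_a]], s, shrinkage, n_null_perm, ns, swaps_per_edge)
            mb = _seven_metrics(pooled[idx[n_a:]], s, shrinkage, n_null_perm, ns, swaps_per_edge)
            null_diffs[p] = ma - mb
        diffs = obs_a - obs_b
        for k, name in enumerate(CURVE_METRICS):
            tail = "greater" if diffs[k] >= 0 else "less"
            rows.append(
                {
                    "sparsity": float(s),
                    "metric": name,
                    "value_a": obs_a[k],
                    "value_b": obs_b[k],
                    "difference": diffs[k],
                    "tail": tail,
                    "p_value": add_one_p(diffs[k], null_diffs[:, k], tail),
                }
            )
    return pd.DataFrame(rows)


def _bi_vector(X: np.ndarray, sparsity: float, shrinkage: float) -> np.ndarray:
    A = binarize_matrix(partial_correlation(X, shrinkage), sparsity)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        _, bi = betweenness_normalized(A)
    return bi


def compare_hub_bi(
    cohort_a: RegionMatrix,
    cohort_b: RegionMatrix,
    sparsity: float = 0.21,
    n_perm: int = 1000,
    seed: int = 0,
    shrinkage: float = 0.5,
    hub_threshold: float = HUB_THRESHOLD,
) -> pd.DataFrame:
    """Per-region two-sided permutation comparison of normalized betweenness.

    The statistic per region is bi_A - bi_B at the fixed sparsity; rows are
    sorted by ascending p, and regions that are hubs (bi > threshold) in
    either group are flagged.
    """
    obs_a = _bi_vector(cohort_a.values, sparsity, shrinkage)
    obs_b = _bi_vector(cohort_b.values, sparsity, shrinkage)
    pooled, n_a, _ = _canonical_pool(cohort_a, cohort_b)
    rng = np.random.default_rng(seed)
    n_regions = len(cohort_a.region_ids)
    null_abs_ge = np.zeros(n_regions, dtype=int)
    obs_diff = obs_a - obs_b
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        diff = _bi_vector(pooled[idx[:n_a]], sparsity, shrinkage) - _bi_vector(
            pooled[idx[n_a:]], sparsity, shrinkage
        )
        null_abs_ge += np.abs(diff) >= np.abs(obs_diff)
    p = (1 + null_abs_ge) / (1 + n_perm)
    out = pd.DataFrame(
        {
            "region_id": list(cohort_a.region_ids),
            "bi_a": obs_a,
            "bi_b": obs_b,
            "difference": obs_diff,
            "p_value": p,
            "hub_a": obs_a > hub_threshold,
            "hub_b": obs_b > hub_threshold,
        }
    )
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
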