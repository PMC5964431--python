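"""Group covariance-network construction.

A cohort's normalized subjects x regions table is reduced to a regions x
regions partial-correlation matrix (diagonal-shrinkage precision estimate,
needed because the number of regions exceeds the number of subjects), which
is then binarized by ranking the absolute off-diagonal values and keeping the
strongest fraction ("sparsity") of possible edges.  Negative correlations
participate through their absolute value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import NumericalError, ParameterError
from .parcellation import RegionMatrix

DEFAULT_SHRINKAGE = 0.5
DEFAULT_SPARSITY = 0.21
SPARSITY_GRID = np.round(np.arange(0.06, 0.401, 0.01), 2)


@dataclass
class GroupNetwork:
    """Partial-correlation matrix R and its sparsity-binarized adjacency A."""

    region_ids: list[int]
    R: np.ndarray
    shrinkage: float
    sparsity: float | None = None
    A: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.region_ids)
        if self.R.shape != (n, n):
            raise ParameterError("R shape must match region_ids")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ParameterError("R must be symmetric")
        if np.abs(self.R).max() > 1 + 1e-9:
            raise ParameterError("partial correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def save_tsv(self, r_path: str | Path, a_path: str | Path | None = None) -> None:
        cols = [str(r) for r in self.region_ids]
        pd.DataFrame(self.R, index=cols, columns=cols).to_csv(
            r_path, sep="\t", float_format="%.12g"
        )
        if a_path is not None and self.A is not None:
            pd.DataFrame(self.A.astype(int), index=cols, columns=cols).to_csv(a_path, sep="\t")


def partial_correlation(X: np.ndarray, shrinkage: float = DEFAULT_SHRINKAGE, use_pinv: bool = False) -> np.ndarray:
    """Partial-correlation matrix of a subjects x regions array.

    The sample covariance S is shrunk toward its diagonal,
    S* = (1 - shrinkage) * S + shrinkage * diag(S), and partial correlations
    are read off the precision matrix Omega = inv(S*):
    R_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj), diagonal set to 1.
    With ``use_pinv`` the Moore-Penrose pseudo-inverse replaces the inverse
    (usable at shrinkage 0 when S is singular, p >= n).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ParameterError("need a 2-D table with at least 4 subjects")
    if not 0 <= shrinkage <= 1:
        raise ParameterError("shrinkage must lie in [0, 1]")
    S = np.cov(X, rowvar=False)
    S_star = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    if use_pinv:
        omega = np.linalg.pinv(S_star, hermitian=True)
    else:
        try:
            omega = np.linalg.inv(S_star)
        except np.linalg.LinAlgError as err:
            raise NumericalError(
                "shrunk covariance is singular; use a positive shrinkage "
                "(regions outnumber subjects) or use_pinv=True"
            ) from err
        # inv() can succeed numerically on an effectively singular matrix;
        # only possible at shrinkage 0 with p >= n, so check only there
        if shrinkage == 0 and np.linalg.cond(S_star) > 1e12:
            raise NumericalError(
                "sample covariance is effectively singular; use a positive "
                "shrinkage or use_pinv=True"
            )
    d = np.sqrt(np.diag(omega))
    R = -omega / np.outer(d, d)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def partial_correlation_matrix(
    cohort: RegionMatrix, shrinkage: float = DEFAULT_SHRINKAGE, use_pinv: bool = False
) -> GroupNetwork:
    """Group network (R only) from a normalized cohort table."""
    if not cohort.normalized:
        warnings.warn(
            "cohort is not flagged normalized; partial correlations assume "
            "whole-brain z-normalized signals",
            UserWarning,
            stacklevel=2,
        )
    R = partial_correlation(cohort.values, shrinkage=shrinkage, use_pinv=use_pinv)
    return GroupNetwork(region_ids=list(cohort.region_ids), R=R, shrinkage=shrinkage)


def edge_count_for_sparsity(n_regions: int, sparsity: float) -> int:
    """floor(sparsity * N(N-1)/2); tiny epsilon guards float representation."""
    m = n_regions * (n_regions - 1) // 2
    return int(math.floor(sparsity * m + 1e-9))


def binarize_matrix(R: np.ndarray, sparsity: float) -> np.ndarray:
    """Binary adjacency keeping the strongest |R| fraction of possible edges.

    Upper-triangle entries are ranked by |R| descending, ties broken by
    ascending (i, j) index pair; exactly floor(sparsity * N(N-1)/2) pairs
    become edges.  Negative correlations participate via absolute value.
    """
    if not 0 < sparsity < 1:
        raise ParameterError(f"sparsity must lie in (0, 1), got {sparsity}")
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    strength = np.abs(R[iu, ju])
    k = edge_count_for_sparsity(n, sparsity)
    # lexsort: last key is primary -> sort by -|R|, then i, then j
    order = np.lexsort((ju, iu, -strength))
    keep = order[:k]
    A = np.zeros((n, n), dtype=np.uint8)
    A[iu[keep], ju[keep]] = 1
    A[ju[keep], iu[keep]] = 1
    return A


def binarize_by_sparsity(net: GroupNetwork, sparsity: float = DEFAULT_SPARSITY) -> GroupNetwork:
    """Return a copy of the network with its adjacency filled at ``sparsity``."""
    A = binarize_matrix(net.R, sparsity)
    return GroupNetwork(
        region_ids=list(net.region_ids),
        R=net.R,
        shrinkage=net.shrinkage,
        sparsity=float(sparsity),
        A=A,
    )


def largest_component_size(A: np.ndarray) -> int:
    """Node count of the largest connected component (1 for an edgeless graph)."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ParameterError("adjacency must be square")
    n_comp, labels = connected_components(csr_matrix(A), directed=False)
    return int(np.bincount(labels, minlength=n_comp).max())


def min_connected_sparsity(
    net: GroupNetwork,
    sparsity_grid: Sequence[float] | None = None,
    min_size: int = 50,
) -> tuple[float | None, pd.DataFrame]:
    """Smallest grid sparsity whose binarized network has a component > min_size.

    Returns (sparsity or None when no grid value qualifies, the full
    component-size-vs-sparsity curve).
    """
    grid = SPARSITY_GRID if sparsity_grid is None else np.asarray(sparsity_grid, float)
    if grid.ndim != 1 or len(grid) == 0 or (np.diff(grid) <= 0).any():
        raise ParameterError("sparsity grid must be strictly ascending")
    if grid[0] <= 0 or grid[-1] >= 1:
        raise ParameterError("sparsity grid must lie within (0, 1)")
    sizes = [largest_component_size(binarize_matrix(net.R, s)) for s in grid]
    curve = pd.DataFrame({"sparsity": grid, "largest_component_size": sizes})
    qualifying = curve.loc[curve["largest_component_size"] > min_size, "sparsity"]
    found = float(qualifying.iloc[0]) if len(qualifying) else None
    return found, curve
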