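"""Synthetic two-cohort generator with controlled covariance structure.

Regional signals are drawn from a multivariate normal whose covariance has a
small-world backbone: a ring lattice with ``backbone_degree`` neighbours per
node, rewired with probability ``rewire_prob``, contributes ``edge_strength``
to each connected off-diagonal entry.  Hub alterations are planted either by
adding long-range ties from a region to a dispersed set of partners
(strengthen) or by zeroing all off-diagonal entries incident to a region
(weaken).
Cohorts can optionally be rendered into small toy volumes over an
ellipsoidal "brain" partitioned into contiguous regions, so the voxel-level
stages of the pipeline run at desk scale.

Defaults model the study conditions this package targets: two cohorts of 22
subjects, 90 regions, SUVR-like signals near 100.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import NumericalError, ParameterError
from .parcellation import AtlasParcellation, RegionMatrix, VolumeImage

MEAN_SIGNAL = 100.0  # SUVR-like positive scale
DEFAULT_DIAGONAL_LOAD = 0.5  # keeps S well conditioned at n=22, p=90

STRENGTHEN = "strengthen"
WEAKEN = "weaken"


@dataclass
class CovarianceSpec:
    """A symmetric positive-definite covariance with a small-world backbone."""

    n_regions: int
    backbone_degree: int
    rewire_prob: float
    edge_strength: float
    diagonal_load: float
    planted_alterations: list[tuple[int, str, float]]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.n_regions, self.n_regions):
            raise ParameterError("covariance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ParameterError("covariance matrix must be symmetric")
        for rid, mode, _mag in self.planted_alterations:
            if not 1 <= rid <= self.n_regions:
                raise ParameterError(f"planted region id {rid} outside 1..{self.n_regions}")
            if mode not in (STRENGTHEN, WEAKEN):
                raise ParameterError(f"unknown alteration mode {mode!r}")

    @property
    def region_ids(self) -> list[int]:
        return list(range(1, self.n_regions + 1))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


@dataclass
class SyntheticCohort:
    """One simulated cohort: its region table plus the spec that produced it."""

    label: str
    region_matrix: RegionMatrix
    seed: int
    spec: CovarianceSpec

    def __post_init__(self) -> None:
        if self.region_matrix.n_regions != self.spec.n_regions:
            raise ParameterError("cohort region count disagrees with its CovarianceSpec")


def _repair_positive_definite(matrix: np.ndarray) -> float:
    """Load the diagonal minimally so all eigenvalues are > 0.

    Adds |min eigenvalue| + 0.01 when the matrix is not positive definite;
    returns the amount added (0.0 when no repair was needed).
    """
    min_eig = float(np.linalg.eigvalsh(matrix)[0])
    if min_eig > 0:
        return 0.0
    bump = abs(min_eig) + 0.01
    matrix[np.diag_indices_from(matrix)] += bump
    if np.linalg.eigvalsh(matrix)[0] <= 0:  # cannot happen by construction
        raise NumericalError("positive-definiteness repair failed")
    return bump


def _strengthen_partners(i: int, n_regions: int) -> list[int]:
    """Dispersed partner indices for a strengthen alteration.

    Every ``max(2, n_regions // 18)``-th region around the ring, giving
    roughly 15-20 long-range partners at the default 90 regions.
    """
    step = max(2, n_regions // 18)
    return [(i + j) % n_regions for j in range(step, n_regions, step)]


def build_group_covariance(
    n_regions: int = 90,
    backbone_degree: int = 8,
    rewire_prob: float = 0.05,
    edge_strength: float = 0.3,
    planted_alterations: list[tuple[int, str, float]] | None = None,
    seed: int = 0,
    diagonal_load: float = DEFAULT_DIAGONAL_LOAD,
) -> CovarianceSpec:
    """Build a group covariance from a rewired ring-lattice backbone.

    matrix = I * (1 + diagonal_load) + edge_strength * backbone_adjacency,
    then planted alterations are applied (strengthen: add the magnitude to
    the entries tying the region to a dispersed subset of partners; weaken:
    zero every off-diagonal entry incident to the region) and the diagonal is
    loaded minimally if positive definiteness was lost.
    """
    if n_regions < 4:
        raise ParameterError("n_regions must be at least 4")
    if backbone_degree % 2 != 0:
        raise ParameterError("backbone_degree must be even (ring-lattice neighbours)")
    if not backbone_degree < n_regions:
        raise ParameterError("backbone_degree must be smaller than n_regions")
    if not 0 <= rewire_prob <= 1:
        raise ParameterError("rewire_prob must be in [0, 1]")
    if edge_strength < 0:
        raise ParameterError("edge_strength must be nonnegative")
    if diagonal_load < 0:
        raise ParameterError("diagonal_load must be nonnegative")
    alterations = list(planted_alterations or [])

    graph = nx.watts_strogatz_graph(n_regions, backbone_degree, rewire_prob, seed=seed)
    adjacency = nx.to_numpy_array(graph, nodelist=range(n_regions), dtype=float)

    matrix = np.eye(n_regions) * (1.0 + diagonal_load) + edge_strength * adjacency
    for rid, mode, magnitude in alterations:
        if not 1 <= rid <= n_regions:
            raise ParameterError(f"planted region id {rid} outside 1..{n_regions}")
        i = rid - 1
        if mode == STRENGTHEN:
            # Long-range ties to a dispersed subset of partner regions.  A
            # uniform increment to every incident entry would load the region
            # on the global mean signal, which whole-brain normalization
            # removes exactly; dispersed partners survive normalization and
            # turn the region into a shortcut (high-betweenness) hub.
            for j in _strengthen_partners(i, n_regions):
                matrix[i, j] += magnitude
                matrix[j, i] += magnitude
        elif mode == WEAKEN:
            off = np.arange(n_regions) != i
            matrix[i, off] = 0.0
            matrix[off, i] = 0.0
        else:
            raise ParameterError(f"unknown alteration mode {mode!r}")
    diagonal_load += _repair_positive_definite(matrix)

    return CovarianceSpec(
        n_regions=n_regions,
        backbone_degree=backbone_degree,
        rewire_prob=rewire_prob,
        edge_strength=edge_strength,
        diagonal_load=diagonal_load,
        planted_alterations=alterations,
        matrix=matrix,
    )


def strengthen_pair(spec: CovarianceSpec, region_a: int, region_b: int, delta: float) -> CovarianceSpec:
    """Return a new spec with the covariance between two regions increased.

    Plants a pairwise connectivity increase (e.g. seed-to-target) on top of an
    existing spec; positive definiteness is repaired the same way as in
    :func:`build_group_covariance`.
    """
    if region_a == region_b:
        raise ParameterError("regions must differ")
    for rid in (region_a, region_b):
        if not 1 <= rid <= spec.n_regions:
            raise ParameterError(f"region id {rid} outside 1..{spec.n_regions}")
    matrix = spec.matrix.copy()
    i, j = region_a - 1, region_b - 1
    matrix[i, j] += delta
    matrix[j, i] += delta
    load = spec.diagonal_load + _repair_positive_definite(matrix)
    return CovarianceSpec(
        n_regions=spec.n_regions,
        backbone_degree=spec.backbone_degree,
        rewire_prob=spec.rewire_prob,
        edge_strength=spec.edge_strength,
        diagonal_load=load,
        planted_alterations=list(spec.planted_alterations),
        matrix=matrix,
    )


def sample_region_matrix(
    spec: CovarianceSpec, n_subjects: int = 22, seed: int = 0, label_prefix: str = "sub"
) -> RegionMatrix:
    """Draw independent subjects from N(mean 100, spec.matrix)."""
    if n_subjects < 4:
        raise ParameterError("n_subjects must be at least 4")
    if spec.min_eigenvalue() <= 0:
        raise ParameterError("covariance spec is not positive definite")
    rng = np.random.default_rng(seed)
    mean = np.full(spec.n_regions, MEAN_SIGNAL)
    values = rng.multivariate_normal(mean, spec.matrix, size=n_subjects, method="cholesky")
    return RegionMatrix(
        values=values,
        subject_ids=[f"{label_prefix}-{i + 1:03d}" for i in range(n_subjects)],
        region_ids=spec.region_ids,
        normalized=False,
    )


def _ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Centered ellipsoidal mask with semi-axes 0.45 * grid extent."""
    coords = np.indices(grid_shape, dtype=float)
    center = [(s - 1) / 2.0 for s in grid_shape]
    semi = [0.45 * s for s in grid_shape]
    dist2 = sum(((c - m) / a) ** 2 for c, m, a in zip(coords, center, semi))
    return dist2 <= 1.0


def make_toy_atlas(
    grid_shape: tuple[int, int, int] = (24, 24, 24), n_regions: int = 90, seed: int = 0
) -> AtlasParcellation:
    """Partition an ellipsoidal brain mask into contiguous labelled regions.

    Regions are grown from seeded voxels by a deterministic multi-source BFS
    (6-connectivity), so every region is contiguous, non-empty and the regions
    exhaust the mask.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3:
        raise ParameterError("grid_shape must have three dimensions")
    if int(np.prod(grid_shape)) < 2 * n_regions:
        raise ParameterError("grid too small for the requested number of regions")
    mask = _ellipsoid_mask(grid_shape)
    mask_voxels = np.argwhere(mask)
    if mask_voxels.shape[0] < 2 * n_regions:
        raise ParameterError(
            f"brain mask has {mask_voxels.shape[0]} voxels; need >= {2 * n_regions}"
        )

    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(mask_voxels.shape[0], size=n_regions, replace=False)
    labels = np.zeros(grid_shape, dtype=np.int32)
    queue: deque[tuple[int, int, int]] = deque()
    for rid, idx in enumerate(seed_idx, start=1):
        x, y, z = map(int, mask_voxels[idx])
        labels[x, y, z] = rid
        queue.append((x, y, z))

    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while queue:
        x, y, z = queue.popleft()
        rid = labels[x, y, z]
        for dx, dy, dz in offsets:
            nx_, ny_, nz_ = x + dx, y + dy, z + dz
            if 0 <= nx_ < grid_shape[0] and 0 <= ny_ < grid_shape[1] and 0 <= nz_ < grid_shape[2]:
                if mask[nx_, ny_, nz_] and labels[nx_, ny_, nz_] == 0:
                    labels[nx_, ny_, nz_] = rid
                    queue.append((nx_, ny_, nz_))

    if (labels[mask] == 0).any():  # ellipsoid is 6-connected, so unreachable
        raise NumericalError("region growing left unlabelled mask voxels")
    return AtlasParcellation(labels=labels, region_ids=list(range(1, n_regions + 1)))


def render_subject_volumes(
    region_matrix: RegionMatrix,
    atlas: AtlasParcellation,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[VolumeImage]:
    """Paint each subject's region values into the atlas grid plus voxel noise.

    Every voxel of region r takes the subject's region-r value plus independent
    Gaussian noise of standard deviation ``noise_sd``; background voxels are 0.
    """
    if region_matrix.n_regions != atlas.n_regions:
        raise ParameterError(
            f"region matrix has {region_matrix.n_regions} regions, atlas {atlas.n_regions}"
        )
    if noise_sd < 0:
        raise ParameterError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    mask = atlas.mask
    # lookup[label] -> column index; labels are 1..N in region_ids order
    lookup = np.zeros(max(atlas.region_ids) + 1, dtype=int)
    for col, rid in enumerate(atlas.region_ids):
        lookup[rid] = col
    volumes = []
    for row in region_matrix.values:
        vol = np.zeros(atlas.labels.shape, dtype=float)
        vol[mask] = row[lookup[atlas.labels[mask]]]
        if noise_sd > 0:
            vol[mask] += rng.normal(0.0, noise_sd, size=int(mask.sum()))
        volumes.append(VolumeImage(vol, atlas.voxel_size_mm, atlas.affine))
    return volumes


@dataclass
class StudySpec:
    """Two-cohort study description used by the simulate pipeline stage."""

    n_subjects: int = 22
    n_regions: int = 90
    backbone_degree: int = 8
    rewire_prob: float = 0.05
    edge_strength: float = 0.3
    diagonal_load: float = DEFAULT_DIAGONAL_LOAD
    alterations_a: list[tuple[int, str, float]] = field(default_factory=list)
    alterations_b: list[tuple[int, str, float]] = field(default_factory=list)
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    noise_sd: float = 0.5


def simulate_study(
    study: StudySpec, seed: int = 0
) -> tuple[SyntheticCohort, SyntheticCohort, AtlasParcellation, list[VolumeImage], list[VolumeImage]]:
    """Generate two cohorts sharing a backbone (seeded identically) plus volumes."""
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    common = dict(
        n_regions=study.n_regions,
        backbone_degree=study.backbone_degree,
        rewire_prob=study.rewire_prob,
        edge_strength=study.edge_strength,
        diagonal_load=study.diagonal_load,
        seed=seed,  # same backbone wiring for both groups
    )
    spec_a = build_group_covariance(planted_alterations=study.alterations_a, **common)
    spec_b = build_group_covariance(planted_alterations=study.alterations_b, **common)
    cohort_a = SyntheticCohort(
        "A", sample_region_matrix(spec_a, study.n_subjects, sub[0], "A"), sub[0], spec_a
    )
    cohort_b = SyntheticCohort(
        "B", sample_region_matrix(spec_b, study.n_subjects, sub[1], "B"), sub[1], spec_b
    )
    atlas = make_toy_atlas(study.grid_shape, study.n_regions, seed=seed)
    vols_a = render_subject_volumes(cohort_a.region_matrix, atlas, study.noise_sd, sub[2])
    vols_b = render_subject_volumes(cohort_b.region_matrix, atlas, study.noise_sd, sub[3])
    return cohort_a, cohort_b, atlas, vols_a, vols_b
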