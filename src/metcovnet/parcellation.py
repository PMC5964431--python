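"""Volumetric preprocessing and reduction to regional signal vectors.

Per-subject volumetric images (e.g. FDG-PET SUVR maps already registered to
a common template space) are smoothed, optionally grayscale-rescaled, reduced
to per-region mean intensities through an integer-labelled parcellation, and
z-normalized against the subject's whole-brain (in-mask) mean and standard
deviation.  The result is a subjects x regions :class:`RegionMatrix`, the
input to group covariance-network construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DataError, ParameterError

_FWHM_TO_SIGMA = math.sqrt(8.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class VolumeImage:
    """A 3-D intensity grid with voxel size and a voxel-to-world affine."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ParameterError("volume must be a non-empty 3-D grid")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ParameterError(f"voxel sizes must be three positive values, got {vs}")
        self.voxel_size_mm = vs
        if self.affine is None:
            self.affine = np.diag([vs[0], vs[1], vs[2], 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ParameterError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class AtlasParcellation:
    """Integer-labelled volume mapping voxels to regions 1..N (0 = background)."""

    labels: np.ndarray
    region_ids: list[int]
    region_names: list[str] = field(default_factory=list)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("atlas labels must be integers")
        if self.labels.ndim != 3:
            raise ParameterError("atlas labels must form a 3-D grid")
        if (self.labels < 0).any():
            raise ParameterError("atlas labels must be nonnegative")
        self.region_ids = [int(r) for r in self.region_ids]
        present = set(np.unique(self.labels).tolist()) - {0}
        declared = set(self.region_ids)
        if not present <= declared:
            raise DataError(f"labels {sorted(present - declared)} not in region_ids")
        missing = declared - present
        if missing:
            raise DataError(f"regions {sorted(missing)} have no voxels")
        if not self.region_names:
            self.region_names = [f"region_{r:03d}" for r in self.region_ids]
        if len(self.region_names) != len(self.region_ids):
            raise ParameterError("region_names length must match region_ids")
        if self.affine is None:
            vs = self.voxel_size_mm
            self.affine = np.diag([vs[0], vs[1], vs[2], 1.0])

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean in-brain mask (any nonzero label)."""
        return self.labels > 0

    def region_sizes(self) -> np.ndarray:
        """Voxel count per region, ordered like ``region_ids``."""
        counts = np.bincount(self.labels.ravel(), minlength=max(self.region_ids) + 1)
        return counts[np.asarray(self.region_ids)]


@dataclass
class RegionMatrix:
    """Subjects x regions signal table for one cohort."""

    values: np.ndarray
    subject_ids: list[str]
    region_ids: list[int]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("region matrix must be 2-D (subjects x regions)")
        if not np.isfinite(self.values).all():
            raise DataError("region matrix contains missing/non-finite entries")
        n_subj, n_reg = self.values.shape
        if len(self.subject_ids) != n_subj:
            raise ParameterError("subject_ids length must match row count")
        if len(self.region_ids) != n_reg:
            raise ParameterError("region_ids length must match column count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=[str(r) for r in self.region_ids],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "RegionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            subject_ids=[str(s) for s in df.index],
            region_ids=[int(c) for c in df.columns],
            normalized=normalized,
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def load_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(
        values=np.asarray(img.dataobj, dtype=float),
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine),
    )


def save_volume(vol: VolumeImage, path: str | Path) -> None:
    # float64 on disk: volume round trips must be lossless
    nib.Nifti1Image(vol.values.astype(np.float64), vol.affine).to_filename(str(path))


def load_atlas(nifti_path: str | Path, names_tsv: str | Path | None = None) -> AtlasParcellation:
    img = nib.load(str(nifti_path))
    labels = np.rint(np.asarray(img.dataobj)).astype(np.int32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    region_ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    names: list[str] = []
    if names_tsv is not None:
        tbl = pd.read_csv(names_tsv, sep="\t")
        by_id = dict(zip(tbl["region_id"].astype(int), tbl["name"].astype(str)))
        names = [by_id.get(r, f"region_{r:03d}") for r in region_ids]
    return AtlasParcellation(
        labels=labels,
        region_ids=region_ids,
        region_names=names,
        voxel_size_mm=zooms,
        affine=np.asarray(img.affine),
    )


def save_atlas(atlas: AtlasParcellation, nifti_path: str | Path, names_tsv: str | Path | None = None) -> None:
    nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine).to_filename(str(nifti_path))
    if names_tsv is not None:
        pd.DataFrame({"region_id": atlas.region_ids, "name": atlas.region_names}).to_csv(
            names_tsv, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------


def smooth_volume(img: VolumeImage, fwhm_mm: Sequence[float]) -> VolumeImage:
    """Convolve with a separable Gaussian of the given per-axis FWHM (mm).

    sigma (voxels) = FWHM / (voxel size * sqrt(8 ln 2)); boundaries handled by
    edge replication so the interior mass of an impulse is conserved.
    """
    fwhm = tuple(float(f) for f in fwhm_mm)
    if len(fwhm) != 3 or any(f <= 0 for f in fwhm):
        raise ParameterError(f"fwhm_mm must be three positive values, got {fwhm}")
    sigma_vox = [f / (v * _FWHM_TO_SIGMA) for f, v in zip(fwhm, img.voxel_size_mm)]
    out = ndimage.gaussian_filter(img.values, sigma=sigma_vox, mode="nearest")
    return VolumeImage(out, img.voxel_size_mm, img.affine)


def rescale_grayscale(img: VolumeImage, lo: float = 0.0, hi: float = 255.0) -> VolumeImage:
    """Linear min-max map of intensities onto [lo, hi].

    A constant volume maps to ``lo`` (degenerate-range convention).
    """
    if not hi > lo:
        raise ParameterError(f"hi ({hi}) must exceed lo ({lo})")
    vmin = float(img.values.min())
    vmax = float(img.values.max())
    if vmax == vmin:
        out = np.full_like(img.values, lo)
    else:
        out = lo + (img.values - vmin) * (hi - lo) / (vmax - vmin)
    return VolumeImage(out, img.voxel_size_mm, img.affine)


def extract_region_means(img: VolumeImage, atlas: AtlasParcellation) -> np.ndarray:
    """Arithmetic mean of the image over each atlas region, in region_id order."""
    if img.values.shape != atlas.labels.shape:
        raise ParameterError(
            f"image shape {img.values.shape} != atlas shape {atlas.labels.shape}"
        )
    labels = atlas.labels.ravel()
    vals = img.values.ravel()
    minlength = max(atlas.region_ids) + 1
    counts = np.bincount(labels, minlength=minlength)
    sums = np.bincount(labels, weights=vals, minlength=minlength)
    ids = np.asarray(atlas.region_ids)
    empty = ids[counts[ids] == 0]
    if empty.size:
        raise DataError(f"region {int(empty[0])} has no voxels")
    return sums[ids] / counts[ids]


def brain_statistics(img: VolumeImage, atlas: AtlasParcellation) -> tuple[float, float]:
    """Mean and (population) SD of the image over in-mask (label > 0) voxels."""
    if img.values.shape != atlas.labels.shape:
        raise ParameterError("image and atlas shapes differ")
    in_mask = img.values[atlas.mask]
    if in_mask.size == 0:
        raise DataError("atlas mask is empty")
    return float(in_mask.mean()), float(in_mask.std())


def normalize_subject_signals(
    region_means: np.ndarray, brain_mean: float, brain_sd: float
) -> np.ndarray:
    """Whole-brain z-normalization: (region means - brain mean) / brain SD."""
    if not brain_sd > 0:
        raise DataError(f"whole-brain SD must be positive, got {brain_sd}")
    return (np.asarray(region_means, dtype=float) - brain_mean) / brain_sd


def normalize_region_matrix(
    rm: RegionMatrix, region_weights: np.ndarray | None = None
) -> RegionMatrix:
    """Per-subject z-normalization of a region table.

    Each row is centred on its (optionally voxel-count weighted) mean and
    scaled by its population SD, mirroring whole-brain normalization when the
    table was produced by region-mean extraction.  With ``region_weights``
    equal to the atlas region sizes this reproduces the in-mask voxel
    statistics of a noise-free rendering exactly.
    """
    X = rm.values
    if region_weights is None:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
    else:
        w = np.asarray(region_weights, dtype=float)
        if w.shape != (rm.n_regions,) or (w <= 0).any():
            raise ParameterError("region_weights must be positive, one per region")
        w = w / w.sum()
        mu = (X * w).sum(axis=1, keepdims=True)
        sd = np.sqrt((((X - mu) ** 2) * w).sum(axis=1, keepdims=True))
    if (sd <= 0).any():
        bad = rm.subject_ids[int(np.argmax(sd.ravel() <= 0))]
        raise DataError(f"subject {bad!r} has zero whole-brain SD")
    return RegionMatrix(
        values=(X - mu) / sd,
        subject_ids=list(rm.subject_ids),
        region_ids=list(rm.region_ids),
        normalized=True,
    )


def volumes_to_region_matrix(
    volumes: Sequence[VolumeImage],
    atlas: AtlasParcellation,
    subject_ids: Sequence[str] | None = None,
    fwhm_mm: Sequence[float] | None = None,
    grayscale: bool = False,
    grayscale_range: tuple[float, float] = (0.0, 255.0),
    reference_region: int | None = None,
    normalize: bool = True,
) -> RegionMatrix:
    """Full preprocessing chain: smooth -> grayscale -> extract -> normalize.

    ``reference_region`` optionally divides each volume by that region's mean
    before anything else (SUVR-style reference scaling).  Whole-brain
    statistics for the normalization step are computed over in-mask voxels of
    the processed volume.
    """
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(volumes))]
    rows = []
    for vol in volumes:
        if reference_region is not None:
            ref = extract_region_means(vol, atlas)[atlas.region_ids.index(reference_region)]
            if ref == 0:
                raise DataError(f"reference region {reference_region} has zero mean")
            vol = VolumeImage(vol.values / ref, vol.voxel_size_mm, vol.affine)
        if fwhm_mm is not None:
            vol = smooth_volume(vol, fwhm_mm)
        if grayscale:
            vol = rescale_grayscale(vol, *grayscale_range)
        means = extract_region_means(vol, atlas)
        if normalize:
            mu, sd = brain_statistics(vol, atlas)
            means = normalize_subject_signals(means, mu, sd)
        rows.append(means)
    return RegionMatrix(
        values=np.vstack(rows),
        subject_ids=list(subject_ids),
        region_ids=list(atlas.region_ids),
        normalized=normalize,
    )
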