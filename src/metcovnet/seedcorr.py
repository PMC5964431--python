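"""Seed-based voxel-wise correlation and between-group Fisher-z comparison.

For each group, the mean signal of a seed region is correlated across
subjects with every in-mask voxel (Pearson r).  The r-maps are Fisher
r-to-z transformed, z = arctanh(r), and compared between groups with the
two-sample statistic

    z_diff = (z1 - z2) / sqrt(1/(n1 - 3) + 1/(n2 - 3)),

which is standard normal under the null.  Two-sided p-values are corrected
with Benjamini-Hochberg FDR at level q over the in-mask voxels that carry a
test (zero-variance voxels are excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, ParameterError
from .parcellation import AtlasParcellation, VolumeImage, save_volume

_CLIP = 1.0 - 1e-7


@dataclass
class SeedMaps:
    """Per-group r/z maps, the between-group z map, p map and FDR masks."""

    seed_region_id: int
    r_map_a: np.ndarray
    r_map_b: np.ndarray
    z_map_a: np.ndarray
    z_map_b: np.ndarray
    z_diff_map: np.ndarray
    p_map: np.ndarray
    fdr_mask: np.ndarray
    strengthened_mask: np.ndarray
    weakened_mask: np.ndarray
    valid_mask: np.ndarray
    n_a: int
    n_b: int
    q: float

    def save(self, out_dir: str | Path, atlas: AtlasParcellation) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        named = {
            "r_map_a": self.r_map_a,
            "r_map_b": self.r_map_b,
            "z_diff_map": self.z_diff_map,
            "p_map": self.p_map,
            "fdr_mask": self.fdr_mask.astype(float),
            "strengthened_mask": self.strengthened_mask.astype(float),
            "weakened_mask": self.weakened_mask.astype(float),
        }
        for name, arr in named.items():
            save_volume(
                VolumeImage(arr, atlas.voxel_size_mm, atlas.affine), out / f"{name}.nii.gz"
            )


def cluster_summary(maps: "SeedMaps") -> pd.DataFrame:
    """Connected components of the FDR mask with voxel counts and peaks.

    One row per cluster (6-connectivity): voxel count, sign of the effect,
    peak |z_diff| value and its voxel coordinates.  Empty masks give an empty
    table.
    """
    labels, n_clusters = ndimage.label(maps.fdr_mask)
    rows = []
    for k in range(1, n_clusters + 1):
        inside = labels == k
        z = maps.z_diff_map[inside]
        peak_flat = np.argmax(np.abs(z))
        coords = np.argwhere(inside)[peak_flat]
        rows.append(
            {
                "cluster_id": k,
                "n_voxels": int(inside.sum()),
                "direction": "strengthened" if z[peak_flat] > 0 else "weakened",
                "peak_z": float(z[peak_flat]),
                "peak_x": int(coords[0]),
                "peak_y": int(coords[1]),
                "peak_z_index": int(coords[2]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_voxels", "direction", "peak_z",
            "peak_x", "peak_y", "peak_z_index",
        ],
    )


def seed_rmap(
    volumes: Sequence[VolumeImage], atlas: AtlasParcellation, seed_region_id: int
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise Pearson correlation with the seed region's mean signal.

    Returns (r volume, valid mask).  Per subject the seed value is the mean
    intensity over the seed region; per in-mask voxel r is the correlation
    across subjects between seed values and voxel values.  Voxels (or seeds)
    with zero variance get r = 0 and are excluded from the valid mask.
    """
    if len(volumes) < 4:
        raise ParameterError("need at least 4 subjects")
    if seed_region_id not in atlas.region_ids:
        raise DataError(f"seed region {seed_region_id} not in atlas")
    mask = atlas.mask
    seed_vox = atlas.labels == seed_region_id
    if not seed_vox.any():
        raise DataError(f"seed region {seed_region_id} is empty")
    data = np.stack([v.values for v in volumes])  # subjects x voxels grid
    if data.shape[1:] != atlas.labels.shape:
        raise ParameterError("volume grids must match the atlas grid")
    seed_vals = data[:, seed_vox].mean(axis=1)
    X = data[:, mask]  # subjects x in-mask voxels
    Xc = X - X.mean(axis=0)
    sc = seed_vals - seed_vals.mean()
    vox_norm = np.sqrt((Xc**2).sum(axis=0))
    seed_norm = np.sqrt((sc**2).sum())
    valid_flat = vox_norm > 0
    if seed_norm == 0:
        valid_flat &= False
    r_flat = np.zeros(X.shape[1])
    if seed_norm > 0:
        np.divide(sc @ Xc, vox_norm * seed_norm, out=r_flat, where=valid_flat)
    r_map = np.zeros(atlas.labels.shape)
    r_map[mask] = np.clip(r_flat, -1.0, 1.0)
    valid = np.zeros(atlas.labels.shape, dtype=bool)
    valid[mask] = valid_flat
    return r_map, valid


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform z = 0.5 * ln((1+r)/(1-r)) = arctanh(r).

    |r| >= 1 is clipped to +/-(1 - 1e-7) with a warning (degenerate
    self-correlation voxels).
    """
    arr = np.asarray(r, dtype=float)
    n_clipped = int(np.sum(np.abs(arr) >= 1.0))
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} correlation(s) with |r| >= 1", UserWarning, stacklevel=2)
    out = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return float(out) if np.isscalar(r) else out


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    """Inverse transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def z_compare(
    z1: np.ndarray | float, z2: np.ndarray | float, n1: int, n2: int
) -> np.ndarray | float:
    """Two-sample comparison of Fisher-z values: (z1 - z2)/sqrt(1/(n1-3)+1/(n2-3))."""
    if n1 <= 3 or n2 <= 3:
        raise ParameterError("both group sizes must exceed 3")
    denom = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    out = (np.asarray(z1, dtype=float) - np.asarray(z2, dtype=float)) / denom
    return float(out) if np.isscalar(z1) and np.isscalar(z2) else out


def fdr_mask(p_map: np.ndarray, q: float = 0.05, mask: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at level q over the in-mask voxels."""
    p_map = np.asarray(p_map, dtype=float)
    if mask is None:
        mask = np.ones(p_map.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("mask is empty")
    if not 0 < q < 1:
        raise ParameterError("q must lie in (0, 1)")
    p = p_map[mask]
    if ((p <= 0) | (p > 1)).any():
        raise DataError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    out = np.zeros(p_map.shape, dtype=bool)
    out[mask] = reject
    return out


def seed_group_compare(
    volumes_a: Sequence[VolumeImage],
    volumes_b: Sequence[VolumeImage],
    atlas: AtlasParcellation,
    seed_region_id: int,
    q: float = 0.05,
) -> SeedMaps:
    """Full seed analysis: r-maps per group, Fisher z, Z comparison, FDR masks.

    The strengthened mask covers FDR-significant voxels with z_diff > 0
    (group A's seed coupling exceeds group B's) and the weakened mask those
    with z_diff < 0.
    """
    if len(volumes_a) < 4 or len(volumes_b) < 4:
        raise ParameterError("both groups need at least 4 subjects")
    r_a, valid_a = seed_rmap(volumes_a, atlas, seed_region_id)
    r_b, valid_b = seed_rmap(volumes_b, atlas, seed_region_id)
    valid = valid_a & valid_b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        z_a = fisher_z(r_a)
        z_b = fisher_z(r_b)
    z_diff = np.zeros(r_a.shape)
    z_diff[valid] = z_compare(z_a[valid], z_b[valid], len(volumes_a), len(volumes_b))
    p_map = np.ones(r_a.shape)
    p_map[valid] = 2.0 * sps.norm.sf(np.abs(z_diff[valid]))
    p_map[valid] = np.clip(p_map[valid], np.finfo(float).tiny, 1.0)
    sig = fdr_mask(p_map, q=q, mask=valid)
    return SeedMaps(
        seed_region_id=seed_region_id,
        r_map_a=r_a,
        r_map_b=r_b,
        z_map_a=z_a,
        z_map_b=z_b,
        z_diff_map=z_diff,
        p_map=p_map,
        fdr_mask=sig,
        strengthened_mask=sig & (z_diff > 0),
        weakened_mask=sig & (z_diff < 0),
        valid_mask=valid,
        n_a=len(volumes_a),
        n_b=len(volumes_b),
        q=q,
    )
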