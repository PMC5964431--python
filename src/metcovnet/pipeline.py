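"""End-to-end orchestration: simulate-or-load -> preprocess -> networks ->
metrics -> group statistics -> seed maps, driven by one YAML config.

A single master seed deterministically spawns a per-stage seed via
numpy's SeedSequence keyed on (master seed, stage index), so every stage is
independently re-runnable and the whole run is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .exceptions import ParameterError
from .metrics import compute_metric_set, detect_hubs
from .network import (
    binarize_by_sparsity,
    largest_component_size,
    min_connected_sparsity,
    partial_correlation_matrix,
)
from .parcellation import (
    AtlasParcellation,
    RegionMatrix,
    VolumeImage,
    load_atlas,
    load_volume,
    normalize_region_matrix,
    save_atlas,
    save_volume,
    volumes_to_region_matrix,
)
from .seedcorr import cluster_summary, seed_group_compare
from .stats import compare_hub_bi, metric_sparsity_curves
from .synthetic import StudySpec, simulate_study

STAGES = ("simulate", "preprocess", "network", "metrics", "group_stats", "seed_maps")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    mode: str = "simulate"  # simulate | tables | volumes
    # input paths (tables / volumes modes)
    table_a: str | None = None
    table_b: str | None = None
    volumes_a: str | None = None
    volumes_b: str | None = None
    atlas: str | None = None
    atlas_names: str | None = None
    # preprocessing
    fwhm_mm: tuple[float, float, float] | None = None
    grayscale: bool = False
    grayscale_lo: float = 0.0
    grayscale_hi: float = 255.0
    reference_region: int | None = None
    # network
    shrinkage: float = 0.5
    sparsity: float = 0.21
    sparsity_grid: tuple[float, float, float] = (0.06, 0.40, 0.01)
    min_component_size: int = 50
    # metrics / statistics
    n_null: int = 200
    n_null_perm: int = 10
    n_perm_curves: int = 2000
    n_perm_hubs: int = 1000
    swaps_per_edge: int = 10
    hub_threshold: float = 1.5
    # seed correlation
    seed_region_id: int = 1
    q: float = 0.05
    # reproducibility
    seed: int = 0
    # simulate-mode study description
    study: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "tables", "volumes"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if not 0 < self.sparsity < 1:
            raise ParameterError("sparsity must lie in (0, 1)")
        if not 0 <= self.shrinkage <= 1:
            raise ParameterError("shrinkage must lie in [0, 1]")
        if not 0 < self.q < 1:
            raise ParameterError("q must lie in (0, 1)")
        for key in ("n_null", "n_null_perm", "n_perm_curves", "n_perm_hubs"):
            if getattr(self, key) < 1:
                raise ParameterError(f"{key} must be positive")
        if self.mode == "tables" and not (self.table_a and self.table_b):
            raise ParameterError("tables mode needs table_a and table_b")
        if self.mode == "volumes" and not (self.volumes_a and self.volumes_b and self.atlas):
            raise ParameterError("volumes mode needs volumes_a, volumes_b and atlas")

    @property
    def grid(self) -> np.ndarray:
        lo, hi, step = self.sparsity_grid
        return np.round(np.arange(lo, hi + step / 2, step), 6)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "fwhm_mm" in raw and raw["fwhm_mm"] is not None:
            raw["fwhm_mm"] = tuple(raw["fwhm_mm"])
        if "sparsity_grid" in raw:
            raw["sparsity_grid"] = tuple(raw["sparsity_grid"])
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from (master seed, stage index)."""
    idx = STAGES.index(stage)
    state = np.random.SeedSequence([int(master_seed), idx]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def _load_volume_dir(path: str) -> list[VolumeImage]:
    files = sorted(Path(path).glob("*.nii*"))
    if not files:
        raise ParameterError(f"no NIfTI volumes found under {path}")
    return [load_volume(f) for f in files]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute all stages in order; write reports, maps and a manifest.

    Returns the manifest dictionary.  Stage failures raise with the stage
    name; outputs produced so far are kept and the manifest is written with a
    ``failed_stage`` marker.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages_completed": [],
    }
    try:
        _run_stages(config, out, manifest)
    except Exception as err:  # annotate and keep partial outputs
        manifest["failed_stage"] = manifest.get("current_stage", "unknown")
        manifest["error"] = f"{type(err).__name__}: {err}"
        _write_manifest(manifest, out)
        raise
    manifest.pop("current_stage", None)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict[str, Any], out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))


def _run_stages(config: RunConfig, out: Path, manifest: dict[str, Any]) -> None:
    atlas: AtlasParcellation | None = None
    volumes_a: Sequence[VolumeImage] | None = None
    volumes_b: Sequence[VolumeImage] | None = None

    # -- stage 1: simulate or load -----------------------------------------
    manifest["current_stage"] = "simulate"
    if config.mode == "simulate":
        study = StudySpec(**{**config.study, "alterations_a": _alts(config.study.get("alterations_a")),
                             "alterations_b": _alts(config.study.get("alterations_b"))})
        cohort_a, cohort_b, atlas, volumes_a, volumes_b = simulate_study(
            study, seed=stage_seed(config.seed, "simulate")
        )
        raw_a, raw_b = cohort_a.region_matrix, cohort_b.region_matrix
        raw_a.to_tsv(out / "cohort_A_raw.tsv")
        raw_b.to_tsv(out / "cohort_B_raw.tsv")
        save_atlas(atlas, out / "atlas.nii.gz", out / "atlas_regions.tsv")
    elif config.mode == "tables":
        raw_a = RegionMatrix.from_tsv(config.table_a)
        raw_b = RegionMatrix.from_tsv(config.table_b)
    else:  # volumes
        atlas = load_atlas(config.atlas, config.atlas_names)
        volumes_a = _load_volume_dir(config.volumes_a)
        volumes_b = _load_volume_dir(config.volumes_b)
        raw_a = raw_b = None
    manifest["stages_completed"].append("simulate")

    # -- stage 2: preprocess / normalize ------------------------------------
    manifest["current_stage"] = "preprocess"
    if volumes_a is not None and atlas is not None:
        kw = dict(
            fwhm_mm=config.fwhm_mm,
            grayscale=config.grayscale,
            grayscale_range=(config.grayscale_lo, config.grayscale_hi),
            reference_region=config.reference_region,
            normalize=True,
        )
        norm_a = volumes_to_region_matrix(volumes_a, atlas, **kw)
        norm_b = volumes_to_region_matrix(volumes_b, atlas, **kw)
    else:
        norm_a = normalize_region_matrix(raw_a)
        norm_b = normalize_region_matrix(raw_b)
    norm_a.to_tsv(out / "cohort_A_normalized.tsv")
    norm_b.to_tsv(out / "cohort_B_normalized.tsv")
    manifest["stages_completed"].append("preprocess")

    # -- stage 3: group networks --------------------------------------------
    manifest["current_stage"] = "network"
    nets = {}
    for label, cohort in (("A", norm_a), ("B", norm_b)):
        net = partial_correlation_matrix(cohort, shrinkage=config.shrinkage)
        net = binarize_by_sparsity(net, config.sparsity)
        net.save_tsv(out / f"network_{label}_R.tsv", out / f"network_{label}_A.tsv")
        nets[label] = net
    comp = {
        label: {
            "largest_component_size": largest_component_size(net.A),
            "min_connected_sparsity": min_connected_sparsity(
                net, config.grid, config.min_component_size
            )[0],
        }
        for label, net in nets.items()
    }
    manifest["components"] = comp
    manifest["stages_completed"].append("network")

    # -- stage 4: graph metrics ----------------------------------------------
    manifest["current_stage"] = "metrics"
    m_seed = stage_seed(config.seed, "metrics")
    hubs = {}
    for label, net in nets.items():
        ms = compute_metric_set(net.A, n_null=config.n_null, seed=m_seed, swaps_per_edge=config.swaps_per_edge)
        ms.save_json(out / f"metrics_{label}.json")
        ms.node_table(net.region_ids).to_csv(
            out / f"metrics_{label}_nodes.tsv", sep="\t", index=False, float_format="%.12g"
        )
        hubs[label] = [net.region_ids[i] for i in detect_hubs(ms.bi_node, config.hub_threshold)]
    manifest["hubs"] = hubs
    manifest["stages_completed"].append("metrics")

    # -- stage 5: group statistics -------------------------------------------
    manifest["current_stage"] = "group_stats"
    g_seed = stage_seed(config.seed, "group_stats")
    curves = metric_sparsity_curves(
        norm_a,
        norm_b,
        grid=config.grid,
        n_perm=config.n_perm_curves,
        seed=g_seed,
        shrinkage=config.shrinkage,
        n_null=config.n_null,
        n_null_perm=config.n_null_perm,
        swaps_per_edge=config.swaps_per_edge,
    )
    curves.to_csv(out / "metric_curves.tsv", sep="\t", index=False, float_format="%.12g")
    hub_table = compare_hub_bi(
        norm_a,
        norm_b,
        sparsity=config.sparsity,
        n_perm=config.n_perm_hubs,
        seed=g_seed + 1,
        shrinkage=config.shrinkage,
        hub_threshold=config.hub_threshold,
    )
    hub_table.to_csv(out / "hub_comparison.tsv", sep="\t", index=False, float_format="%.12g")
    manifest["stages_completed"].append("group_stats")

    # -- stage 6: seed maps ----------------------------------------------------
    manifest["current_stage"] = "seed_maps"
    if volumes_a is not None and atlas is not None:
        maps = seed_group_compare(volumes_a, volumes_b, atlas, config.seed_region_id, q=config.q)
        maps.save(out / "seed_maps", atlas)
        cluster_summary(maps).to_csv(
            out / "seed_maps" / "clusters.tsv", sep="\t", index=False, float_format="%.6g"
        )
        manifest["seed_maps"] = {
            "seed_region_id": config.seed_region_id,
            "n_significant": int(maps.fdr_mask.sum()),
            "n_strengthened": int(maps.strengthened_mask.sum()),
            "n_weakened": int(maps.weakened_mask.sum()),
        }
    else:
        manifest["seed_maps"] = "skipped (no volumes in tables mode)"
    manifest["stages_completed"].append("seed_maps")


def _alts(raw: Any) -> list[tuple[int, str, float]]:
    """Normalize YAML alteration entries [[region, mode, magnitude], ...]."""
    if not raw:
        return []
    return [(int(r), str(m), float(g)) for r, m, g in raw]
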