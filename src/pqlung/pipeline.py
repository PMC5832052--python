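"""End-to-end orchestration: smooth -> segment -> classify -> de-vessel
-> clean -> volumetrics -> prognostic ratio.

The pipeline applies the same per-scan chain to one or two scans and,
given two, reports the ratio of injured lung volume fractions.  Every
stage parameter lives in :class:`PipelineConfig`; a run log records all
parameters, the config hash, the seed, and the voxel count after every
mask-producing step, so reruns with the same config and seed are
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import injury_classifier, lung_segmentation, preprocessing, vessel_filter, volumetrics
from .injury_classifier import AnnModel
from .volume_io import BinaryMask, CTVolume
from .volumetrics import RatioResult, VolumetricsResult

__all__ = ["PipelineConfig", "ScanResult", "PipelineResult", "run_scan", "run_pipeline"]


@dataclass
class PipelineConfig:
    smooth_iters: int = 10
    smooth_kappa: float = 50.0
    smooth_step: float = 0.15
    grow_coeff: float = 0.3
    grow_window: int = 40
    connectivity: int = 26
    fill_holes: bool = True
    classify_threshold: float = 0.5
    vessel_scales_mm: tuple = (1.0, 2.0, 3.0, 4.0)
    vessel_threshold: float = 0.15
    min_region_voxels: int = 30
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ScanResult:
    volumetrics: VolumetricsResult
    lung: BinaryMask
    injured_candidate: BinaryMask
    vessels: BinaryMask
    injured_final: BinaryMask
    log: list


@dataclass
class PipelineResult:
    scans: list
    ratio: RatioResult | None
    config: PipelineConfig

    def to_dict(self) -> dict:
        out = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "scans": [s.volumetrics.to_dict() for s in self.scans],
        }
        if self.ratio is not None:
            out["ratio"] = self.ratio.to_dict()
        return out


def build_training_dataset(volume: CTVolume, truth: dict,
                           config: PipelineConfig | None = None,
                           max_per_class: int | None = None,
                           seed: int = 0):
    """Labelled features from a truth-annotated volume, pipeline-consistent.

    The volume is smoothed exactly as :func:`run_scan` smooths scans, so
    training features come from the same representation the classifier
    later sees.  Vessel voxels are excluded from both classes (a reader
    annotating injury avoids vessels; the Hessian filter handles them).
    `max_per_class` caps each class by seeded random subsampling.
    """
    from .texture_features import FeatureDataset, build_dataset

    cfg = config or PipelineConfig()
    smoothed = preprocessing.anisotropic_diffusion(
        volume, n_iter=cfg.smooth_iters, kappa=cfg.smooth_kappa, step=cfg.smooth_step)
    lung = truth["lung"]
    vessel_bits = truth["vessel"].bits if "vessel" in truth else np.zeros(lung.shape, bool)
    injured_bits = truth["injured"].bits & ~vessel_bits
    normal_bits = lung.bits & ~truth["injured"].bits & ~vessel_bits
    ds = build_dataset(smoothed, lung,
                       {"injured": injured_bits, "noninjured": normal_bits},
                       provenance=volume.scan_id)
    if max_per_class is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for label in (0, 1):
            idx = np.flatnonzero(ds.labels == label)
            if len(idx) > max_per_class:
                idx = np.sort(rng.choice(idx, max_per_class, replace=False))
            keep.append(idx)
        sel = np.concatenate(keep)
        ds = FeatureDataset(ds.features[sel], ds.labels[sel],
                            coords=None if ds.coords is None else ds.coords[sel],
                            provenance=ds.provenance)
    return ds


def run_scan(volume: CTVolume, seeds, model: AnnModel,
             config: PipelineConfig | None = None) -> ScanResult:
    """Full per-scan chain from raw HU volume to injured-fraction result."""
    cfg = config or PipelineConfig()
    log: list = []

    def note(stage: str, **kw) -> None:
        log.append({"stage": stage, **kw})

    smoothed = preprocessing.anisotropic_diffusion(
        volume, n_iter=cfg.smooth_iters, kappa=cfg.smooth_kappa, step=cfg.smooth_step)
    note("smooth", n_iter=cfg.smooth_iters, kappa=cfg.smooth_kappa)

    seed_pts = [lung_segmentation.SeedPoint.from_volume(smoothed, s)
                if not isinstance(s, lung_segmentation.SeedPoint) else s
                for s in seeds]
    lung = lung_segmentation.segment_both_lungs(
        smoothed, seed_pts, coefficient=cfg.grow_coeff, window_edge=cfg.grow_window,
        connectivity=cfg.connectivity, fill_holes=cfg.fill_holes)
    note("segment_lung", voxels=lung.count())

    candidate = injury_classifier.classify_volume(
        model, smoothed, lung, threshold=cfg.classify_threshold)
    note("classify", voxels=candidate.count())

    vmap = vessel_filter.vesselness(smoothed, scales_mm=cfg.vessel_scales_mm, roi=lung)
    vessels = vessel_filter.segment_vessels(vmap, threshold=cfg.vessel_threshold,
                                            spacing_mm=volume.spacing_mm)
    note("vesselness", voxels=vessels.count())

    devesseled = vessel_filter.remove_vessels(candidate, vessels)
    note("remove_vessels", voxels=devesseled.count())

    injured = volumetrics.remove_small_regions(
        devesseled, min_voxels=cfg.min_region_voxels, connectivity=cfg.connectivity)
    note("remove_small_regions", voxels=injured.count())

    result = volumetrics.injured_fraction(injured, lung, spacing_mm=volume.spacing_mm,
                                          scan_id=volume.scan_id)
    note("volumetrics", fraction=result.injured_fraction)
    return ScanResult(result, lung, candidate, vessels, injured, log)


def run_pipeline(scans: list, seeds_per_scan: list, model: AnnModel,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run one or two scans; compute the fraction ratio when given two.

    `scans` is a list of CTVolume (first = admission, second =
    follow-up); `seeds_per_scan` gives the per-scan seed index lists.
    """
    cfg = config or PipelineConfig()
    if not scans:
        raise ValueError("no scans given")
    if len(scans) > 2:
        raise ValueError("at most two scans (admission + follow-up)")
    if len(seeds_per_scan) != len(scans):
        raise ValueError("need one seed list per scan")
    results = [run_scan(v, s, model, cfg) for v, s in zip(scans, seeds_per_scan)]
    ratio = None
    if len(results) == 2:
        ratio = volumetrics.fraction_ratio(results[0].volumetrics,
                                           results[1].volumetrics)
    out = PipelineResult(results, ratio, cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "results.json").write_text(json.dumps(out.to_dict(), indent=1))
        log = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
               "stages": [s.log for s in results]}
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=1, default=list))
    return out
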