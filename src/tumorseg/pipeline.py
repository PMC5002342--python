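"""End-to-end orchestration of the four segmentation stages.

:func:`segment` runs, on the seed-defined ROI:

1. preprocessing — anisotropic diffusion, Gaussian gradient magnitude,
   sigmoid edge potential (the speed image);
2. teacher-region generation — two competing fast marches (tumor seeds vs
   background seeds) thresholded at the stop value;
3. voxel classification — ELM-trained single-hidden-layer network labels
   every voxel the fronts did not reach;
4. postprocessing — tumor-by-either-stage fusion, seed-component
   extraction, morphological cleanup — and re-embeds the mask on the full
   grid.

Each stage's parameters, voxel counts and wall time are collected in a
provenance record so a run is auditable and reproducible.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from . import elm, fast_marching, postprocess, preprocess
from .config import PipelineConfig
from .metrics import EvaluationReport, evaluate_masks
from .volume import RoiFrame, SeedSet, Volume, embed_roi, extract_roi, write_volume

__all__ = ["segment", "evaluate", "SegmentationResult"]

log = logging.getLogger("tumorseg")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class SegmentationResult:
    """Final mask (full grid) plus volume and provenance."""

    def __init__(self, mask: np.ndarray, volume_cm3: float, provenance: dict,
                 roi_frame: RoiFrame, spacing: tuple[float, float, float]):
        self.mask = mask
        self.volume_cm3 = volume_cm3
        self.provenance = provenance
        self.roi_frame = roi_frame
        self.spacing = spacing


def _stage(name: str, fn, prov: dict):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:
        raise StageError(f"stage '{name}' failed: {exc}") from exc
    prov.setdefault("timings_s", {})[name] = round(time.perf_counter() - t0, 4)
    log.info("stage %-14s done in %.2fs", name, time.perf_counter() - t0)
    return out


def segment(volume: Volume, seeds: SeedSet, config: PipelineConfig | None = None,
            dump_dir=None) -> SegmentationResult:
    """Segment the tumor around the seeds; returns mask, volume and provenance.

    ``dump_dir``, if given, receives the intermediate volumes (noise-reduced
    ROI, gradient magnitude, edge potential, teacher labels) as MetaImage
    files for inspection.
    """
    cfg = config or PipelineConfig()
    prov: dict = {"config": cfg.to_dict()}

    roi, frame, roi_seeds = _stage(
        "roi", lambda: extract_roi(volume, seeds, cfg.margin_mm), prov
    )
    prov["roi_offset"] = list(frame.offset)
    prov["roi_shape"] = list(frame.shape)

    dp = preprocess.DiffusionParams(
        n_steps=cfg.diffusion_steps,
        time_step=cfg.diffusion_time_step,
        conductance=cfg.diffusion_conductance,
    )
    smoothed = _stage("diffusion", lambda: preprocess.anisotropic_diffusion(roi, dp), prov)
    gradmag = _stage(
        "gradient", lambda: preprocess.gradient_magnitude(smoothed, cfg.gradient_sigma_mm), prov
    )
    sp = preprocess.SigmoidParams(alpha=cfg.sigmoid_alpha, beta=cfg.sigmoid_beta)
    speed = _stage("edge_potential", lambda: preprocess.edge_potential(gradmag, sp), prov)

    tt = _stage(
        "march_tumor",
        lambda: fast_marching.fast_march(speed, roi_seeds.tumor, cfg.stop_value),
        prov,
    )
    tb = _stage(
        "march_background",
        lambda: fast_marching.fast_march(speed, roi_seeds.background, cfg.stop_value),
        prov,
    )
    teachers = _stage(
        "label_regions", lambda: fast_marching.label_regions(tt, tb, cfg.stop_value), prov
    )
    prov["teacher_tumor_voxels"] = int(np.count_nonzero(teachers == 1))
    prov["teacher_background_voxels"] = int(np.count_nonzero(teachers == 2))
    prov["unlabeled_voxels"] = int(np.count_nonzero(teachers == 0))

    pattern_src = smoothed if cfg.patterns_from_smoothed else roi
    model = _stage(
        "elm_train",
        lambda: elm.train(pattern_src, teachers, cfg.window, cfg.hidden_size,
                          cfg.ridge, cfg.rng_seed),
        prov,
    )
    full_labels = _stage(
        "elm_classify", lambda: elm.classify(pattern_src, teachers, model, cfg.window), prov
    )

    fused = _stage("fuse", lambda: postprocess.fuse_labels(teachers, full_labels), prov)
    prov["fused_voxels"] = int(np.count_nonzero(fused))
    kept = _stage(
        "seed_component",
        lambda: postprocess.keep_seed_component(fused, roi_seeds.tumor,
                                                cfg.component_connectivity),
        prov,
    )
    cleaned = _stage(
        "morphology", lambda: postprocess.morphological_cleanup(kept, cfg.morphology_radius), prov
    )
    prov["final_voxels"] = int(np.count_nonzero(cleaned))

    full_mask = embed_roi(cleaned, frame)
    vol_cm3 = postprocess.mask_volume(full_mask, volume.spacing)
    prov["volume_cm3"] = vol_cm3

    if dump_dir is not None:
        from pathlib import Path

        d = Path(dump_dir)
        d.mkdir(parents=True, exist_ok=True)
        for name, vol in (
            ("roi_smoothed", smoothed),
            ("gradient_magnitude", gradmag),
            ("edge_potential", speed),
        ):
            write_volume(vol, d / f"{name}.mha")
        write_volume(roi.with_data(teachers), d / "teacher_labels.mha", dtype=np.uint8)
        write_volume(roi.with_data(full_labels), d / "classified_labels.mha", dtype=np.uint8)

    return SegmentationResult(full_mask, vol_cm3, prov, frame, volume.spacing)


def evaluate(seg_mask: np.ndarray, ref_mask: np.ndarray,
             spacing: tuple[float, float, float]) -> EvaluationReport:
    """Evaluate a computed mask against a reference mask on the same grid."""
    return evaluate_masks(seg_mask, ref_mask, spacing)
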