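"""Segmentation evaluation: volume, overlap and surface-distance measures.

Five measures compare a computed mask against a reference mask:

* percentage volume error  ``E = 100 |V_c - V_m| / V_m``
* volumetric overlap error ``VO = 100 (1 - TP / (TP + FP + FN))``
  (the complement of the Jaccard index)
* average / root-mean-square / maximal symmetric surface distance
  (ASSD / RMSSD / MSSD), in mm.

Surface distances use the voxel-border convention: a border voxel is a mask
voxel with at least one face-adjacent background voxel (voxels on the array
boundary count as bordered), distances are Euclidean in mm between border
voxel centers, and the two directed distance sets are pooled before taking
the mean / RMS / max, so ``assd <= rmssd <= mssd`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "EvaluationReport",
    "confusion_counts",
    "percentage_volume_error",
    "volumetric_overlap_error",
    "surface_distances",
    "evaluate_masks",
    "aggregate_reports",
]


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    volume_error_pct: float
    overlap_error_pct: float
    assd_mm: float
    rmssd_mm: float
    mssd_mm: float
    v_c_cm3: float
    v_m_cm3: float

    # column order used for CSV batches
    CSV_COLUMNS = (
        "overlap_error_pct",
        "volume_error_pct",
        "assd_mm",
        "rmssd_mm",
        "mssd_mm",
        "v_c_cm3",
        "v_m_cm3",
        "tp",
        "fp",
        "fn",
    )

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_text(self) -> str:
        return "\n".join(f"{k} {v}" for k, v in self.to_dict().items())

    def csv_row(self) -> str:
        return ",".join(f"{getattr(self, c)}" for c in self.CSV_COLUMNS)


def confusion_counts(seg: np.ndarray, ref: np.ndarray) -> tuple[int, int, int]:
    """(TP, FP, FN) voxel counts between two binary masks on the same grid."""
    seg = np.asarray(seg) > 0
    ref = np.asarray(ref) > 0
    if seg.shape != ref.shape:
        raise ValueError(f"masks have different shapes {seg.shape} vs {ref.shape}")
    tp = int(np.count_nonzero(seg & ref))
    fp = int(np.count_nonzero(seg & ~ref))
    fn = int(np.count_nonzero(~seg & ref))
    return tp, fp, fn


def percentage_volume_error(v_c: float, v_m: float) -> float:
    """100 * |V_c - V_m| / V_m (reference volume must be positive)."""
    if v_m <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * abs(v_c - v_m) / v_m


def volumetric_overlap_error(tp: int, fp: int, fn: int) -> float:
    """100 * (1 - TP / (TP + FP + FN)); undefined for all-zero counts."""
    total = tp + fp + fn
    if total <= 0:
        raise ValueError("overlap error undefined for two empty masks")
    return 100.0 * (1.0 - tp / total)


def border_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (n, 3) of mask voxels with a face-adjacent background voxel."""
    mask = np.asarray(mask) > 0
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return np.argwhere(mask & ~interior)


def surface_distances(seg: np.ndarray, ref: np.ndarray,
                      spacing: Sequence[float]) -> tuple[float, float, float]:
    """(ASSD, RMSSD, MSSD) in mm between two nonempty masks.

    Pooled bidirectional nearest-neighbour distances between border-voxel
    centers, in physical coordinates.
    """
    seg = np.asarray(seg) > 0
    ref = np.asarray(ref) > 0
    if seg.shape != ref.shape:
        raise ValueError(f"masks have different shapes {seg.shape} vs {ref.shape}")
    if not seg.any() or not ref.any():
        raise ValueError("surface distances are undefined for an empty mask")
    sp = np.asarray([float(s) for s in spacing])
    a = border_voxels(seg) * sp
    b = border_voxels(ref) * sp
    d_ab, _ = cKDTree(b).query(a, k=1)
    d_ba, _ = cKDTree(a).query(b, k=1)
    pooled = np.concatenate([d_ab, d_ba])
    return (
        float(pooled.mean()),
        float(np.sqrt(np.mean(pooled**2))),
        float(pooled.max()),
    )


def evaluate_masks(seg: np.ndarray, ref: np.ndarray, spacing: Sequence[float]) -> EvaluationReport:
    """Full report for a computed mask against a reference mask."""
    tp, fp, fn = confusion_counts(seg, ref)
    voxel_cm3 = float(np.prod([float(s) for s in spacing])) / 1000.0
    v_c = float(np.count_nonzero(np.asarray(seg) > 0)) * voxel_cm3
    v_m = float(np.count_nonzero(np.asarray(ref) > 0)) * voxel_cm3
    assd, rmssd, mssd = surface_distances(seg, ref, spacing)
    return EvaluationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        volume_error_pct=percentage_volume_error(v_c, v_m),
        overlap_error_pct=volumetric_overlap_error(tp, fp, fn),
        assd_mm=assd,
        rmssd_mm=rmssd,
        mssd_mm=mssd,
        v_c_cm3=v_c,
        v_m_cm3=v_m,
    )


def aggregate_reports(reports: Sequence[EvaluationReport]) -> dict[str, dict[str, float]]:
    """Mean / SD / min / max per measure over a batch of cases."""
    if not reports:
        raise ValueError("no reports to aggregate")
    out: dict[str, dict[str, float]] = {}
    for col in EvaluationReport.CSV_COLUMNS:
        vals = np.asarray([float(getattr(r, col)) for r in reports], dtype=np.float64)
        out[col] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return out
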