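"""Label fusion, seed-component extraction and morphological cleanup.

A voxel belongs to the tumor if *either* the fast-marching teacher labels or
the network classified it as tumor.  The fused mask is then reduced to the
connected component(s) containing the tumor seeds and cleaned: binary closing,
3-D hole filling, binary opening with a small ball structuring element.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "fuse_labels",
    "keep_seed_component",
    "morphological_cleanup",
    "mask_volume",
    "ball",
]

_CONN_RANK = {6: 1, 18: 2, 26: 3}


def fuse_labels(fm_labels: np.ndarray, elm_labels: np.ndarray) -> np.ndarray:
    """Tumor-by-either-stage union: 1 where either label map equals 1."""
    fm = np.asarray(fm_labels)
    el = np.asarray(elm_labels)
    if fm.shape != el.shape:
        raise ValueError(f"label maps have different shapes {fm.shape} vs {el.shape}")
    return ((fm == 1) | (el == 1)).astype(np.uint8)


def keep_seed_component(mask: np.ndarray, tumor_seeds: Sequence[Sequence[int]],
                        connectivity: int = 26) -> np.ndarray:
    """Keep only the connected component(s) containing tumor seeds.

    If no seed falls on a foreground voxel the result is empty and a warning
    is issued.
    """
    if connectivity not in _CONN_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONN_RANK)}")
    mask = np.asarray(mask) > 0
    struct = ndimage.generate_binary_structure(3, _CONN_RANK[connectivity])
    comp, _ = ndimage.label(mask, structure=struct)
    ids = {int(comp[tuple(int(c) for c in s)]) for s in tumor_seeds}
    ids.discard(0)
    if not ids:
        warnings.warn("no tumor seed lies on a foreground voxel; result is empty", stacklevel=2)
        return np.zeros_like(mask, dtype=np.uint8)
    return np.isin(comp, sorted(ids)).astype(np.uint8)


def ball(radius: int) -> np.ndarray:
    """Discrete ball structuring element of the given voxel radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    x, y, z = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (x * x + y * y + z * z) <= r * r


def morphological_cleanup(mask: np.ndarray, radius_voxels: int = 1) -> np.ndarray:
    """Closing, hole filling, then artifact removal with a ball element.

    Radius 0 only fills holes.  The closing is computed on a zero-padded copy
    so foreground touching the volume border is not clipped.  Artifact removal
    is an opening *by reconstruction*: connected components too thin to
    survive an erosion by the ball are dropped, while surviving components are
    kept with their exact shape (a plain opening would also round off corners
    of legitimate structures, which is not the intent of an artifact filter).
    """
    m = np.asarray(mask) > 0
    if radius_voxels > 0:
        se = ball(radius_voxels)
        r = int(radius_voxels)
        padded = np.pad(m, r, mode="constant")
        m = ndimage.binary_closing(padded, structure=se)[r:-r, r:-r, r:-r]
    m = ndimage.binary_fill_holes(m)
    if radius_voxels > 0:
        eroded = ndimage.binary_erosion(m, structure=se, border_value=0)
        comp, n = ndimage.label(m, structure=ndimage.generate_binary_structure(3, 3))
        keep = np.unique(comp[eroded])
        m = np.isin(comp, keep[keep > 0])
    return m.astype(np.uint8)


def mask_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Mask volume in cm^3: voxel count times voxel volume (mm^3) / 1000."""
    voxels = int(np.count_nonzero(np.asarray(mask)))
    sx, sy, sz = (float(s) for s in spacing)
    return voxels * sx * sy * sz / 1000.0
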