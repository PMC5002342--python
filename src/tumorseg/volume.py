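"""3-D scalar volumes, seed points and region-of-interest extraction.

Conventions
-----------
* Voxel indices are 0-based integer triples in ``(x, y, z)`` order; the
  underlying :class:`numpy.ndarray` is indexed ``data[x, y, z]``.
* ``spacing`` is the physical voxel size in mm per axis; the world position of
  voxel ``(i, j, k)`` is ``origin + index * spacing``.
* Seed files are plain text, one seed per line::

      # lines starting with '#' are comments
      tumor 30 40 25
      background 10 12 8

  with 0-based voxel indices.  1-2 tumor seeds and 1-3 background seeds are
  accepted.
* Binary masks are written as unsigned 8-bit volumes (1 = tumor).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "SeedSet",
    "RoiFrame",
    "read_volume",
    "write_volume",
    "read_seeds",
    "write_seeds",
    "extract_roi",
    "embed_roi",
]

Index = tuple[int, int, int]


@dataclass
class Volume:
    """A 3-D scalar image with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities, indexed ``data[x, y, z]``.
    spacing : (float, float, float)
        Voxel size in mm along (x, y, z); all components must be positive.
    origin : (float, float, float)
        World coordinate (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got {self.data.ndim} axes")
        if min(self.data.shape) < 1:
            raise ValueError("every volume axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Index:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        """Same grid (spacing/origin), new intensities."""
        return Volume(data, self.spacing, self.origin)

    def contains_index(self, idx: Sequence[int]) -> bool:
        return all(0 <= int(i) < n for i, n in zip(idx, self.shape))


@dataclass
class SeedSet:
    """User-placed seed points: 1-2 inside the tumor, 1-3 outside."""

    tumor: list[Index] = field(default_factory=list)
    background: list[Index] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tumor = [tuple(int(c) for c in s) for s in self.tumor]
        self.background = [tuple(int(c) for c in s) for s in self.background]
        if not 1 <= len(self.tumor) <= 2:
            raise ValueError(f"need 1-2 tumor seeds, got {len(self.tumor)}")
        if not 1 <= len(self.background) <= 3:
            raise ValueError(f"need 1-3 background seeds, got {len(self.background)}")
        if set(self.tumor) & set(self.background):
            raise ValueError("tumor and background seed lists must be disjoint")

    def all_seeds(self) -> list[Index]:
        return list(self.tumor) + list(self.background)

    def translated(self, offset: Sequence[int]) -> "SeedSet":
        off = tuple(int(o) for o in offset)
        shift = lambda s: tuple(c - o for c, o in zip(s, off))
        return SeedSet([shift(s) for s in self.tumor], [shift(s) for s in self.background])


@dataclass
class RoiFrame:
    """Mapping between an extracted ROI and the full-volume voxel grid."""

    offset: Index
    shape: Index
    full_shape: Index

    def __post_init__(self) -> None:
        self.offset = tuple(int(o) for o in self.offset)
        self.shape = tuple(int(s) for s in self.shape)
        self.full_shape = tuple(int(s) for s in self.full_shape)
        if any(o < 0 for o in self.offset):
            raise ValueError("ROI offset must be non-negative")
        if any(o + s > f for o, s, f in zip(self.offset, self.shape, self.full_shape)):
            raise ValueError("ROI extends beyond the full volume")

    def to_full(self, idx: Sequence[int]) -> Index:
        return tuple(int(i) + o for i, o in zip(idx, self.offset))


# ---------------------------------------------------------------------------
# File I/O


def _sitk_to_volume(img: sitk.Image, path: str) -> Volume:
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {img.GetDimension()}-D")
    # sitk arrays come back [z, y, x]; transpose to the (x, y, z) convention
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(img.GetSpacing())
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing} in metadata")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains NaN or Inf values")
    return Volume(data, spacing, tuple(img.GetOrigin()))


def _read_dicom_dir(path: str) -> Volume:
    reader = sitk.ImageSeriesReader()
    ids = reader.GetGDCMSeriesIDs(path)
    if not ids:
        raise IOError(f"no DICOM series found in directory {path}")
    files = reader.GetGDCMSeriesFileNames(path, ids[0])
    reader.SetFileNames(files)
    img = reader.Execute()
    if len(files) >= 3:
        # reject inconsistent slice spacing (> 1% deviation between gaps)
        positions = []
        fr = sitk.ImageFileReader()
        for f in files:
            fr.SetFileName(f)
            fr.ReadImageInformation()
            positions.append(np.array([float(v) for v in fr.GetMetaData("0020|0032").split("\\")]))
        gaps = np.linalg.norm(np.diff(np.asarray(positions), axis=0), axis=1)
        if gaps.max() - gaps.min() > 0.01 * gaps.mean():
            raise ValueError(f"{path}: inconsistent inter-slice spacing (range {gaps.min():.4g}-{gaps.max():.4g} mm)")
    return _sitk_to_volume(img, path)


def read_volume(path: str | os.PathLike, format: str = "auto") -> Volume:
    """Read a 3-D volume from MetaImage, NIfTI or a DICOM series directory.

    ``format`` is one of ``auto``, ``metaimage``, ``nifti``, ``dicom_dir``;
    with ``auto`` the format is inferred from the extension (a directory is
    taken as a DICOM series).
    """
    path = str(path)
    if format == "auto":
        if os.path.isdir(path):
            format = "dicom_dir"
        elif path.endswith((".mha", ".mhd")):
            format = "metaimage"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise IOError(f"cannot infer volume format from path {path}")
    if format == "dicom_dir":
        return _read_dicom_dir(path)
    if format not in ("metaimage", "nifti"):
        raise ValueError(f"unknown format {format!r}")
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # sitk raises RuntimeError on unreadable files
        raise IOError(f"could not read volume from {path}: {exc}") from exc
    return _sitk_to_volume(img, path)


def write_volume(volume: Volume, path: str | os.PathLike, dtype=None) -> None:
    """Write a volume as MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz)."""
    data = volume.data if dtype is None else volume.data.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(volume.spacing)
    img.SetOrigin(volume.origin)
    sitk.WriteImage(img, str(path))


def write_mask(mask: np.ndarray, spacing, path: str | os.PathLike, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a binary mask as an unsigned 8-bit volume (1 = tumor)."""
    write_volume(Volume((np.asarray(mask) > 0).astype(np.uint8), spacing, origin), path)


def read_seeds(path: str | os.PathLike) -> SeedSet:
    """Parse a plain-text seed file (see module docstring for the format)."""
    tumor: list[Index] = []
    background: list[Index] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected '<tumor|background> <x> <y> <z>', got {raw!r}")
        kind, *coords = parts
        try:
            idx = tuple(int(c) for c in coords)
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer seed coordinate in {raw!r}") from exc
        if kind == "tumor":
            tumor.append(idx)  # type: ignore[arg-type]
        elif kind == "background":
            background.append(idx)  # type: ignore[arg-type]
        else:
            raise ValueError(f"{path}:{ln}: unknown seed type {kind!r}")
    return SeedSet(tumor, background)


def write_seeds(seeds: SeedSet, path: str | os.PathLike) -> None:
    lines = [f"tumor {s[0]} {s[1]} {s[2]}" for s in seeds.tumor]
    lines += [f"background {s[0]} {s[1]} {s[2]}" for s in seeds.background]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ROI extraction


def extract_roi(volume: Volume, seeds: SeedSet, margin_mm: float = 20.0) -> tuple[Volume, RoiFrame, SeedSet]:
    """Cut the seed-defined region of interest out of the full volume.

    The ROI is the axis-aligned bounding box of all seeds, dilated by
    ``ceil(margin_mm / spacing)`` voxels per axis and clipped to the volume.
    Returns the sub-volume, the frame mapping ROI indices back to the full
    grid, and the seeds translated into ROI coordinates.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    for s in seeds.all_seeds():
        if not volume.contains_index(s):
            raise IndexError(f"seed {s} lies outside the volume of shape {volume.shape}")
    pts = np.asarray(seeds.all_seeds(), dtype=int)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    dil = np.array([ceil(margin_mm / s) for s in volume.spacing], dtype=int)
    lo = np.maximum(lo - dil, 0)
    hi = np.minimum(hi + dil, np.array(volume.shape) - 1)
    shape = hi - lo + 1
    frame = RoiFrame(tuple(lo), tuple(shape), volume.shape)
    sub = volume.data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1].copy()
    origin = tuple(o + l * sp for o, l, sp in zip(volume.origin, lo, volume.spacing))
    return Volume(sub, volume.spacing, origin), frame, seeds.translated(lo)


def embed_roi(mask: np.ndarray, frame: RoiFrame) -> np.ndarray:
    """Place an ROI-sized mask back onto the full-volume grid (zeros outside)."""
    mask = np.asarray(mask)
    if tuple(mask.shape) != frame.shape:
        raise ValueError(f"mask shape {mask.shape} does not match ROI shape {frame.shape}")
    full = np.zeros(frame.full_shape, dtype=mask.dtype)
    o, s = frame.offset, frame.shape
    full[o[0] : o[0] + s[0], o[1] : o[1] + s[1], o[2] : o[2] + s[2]] = mask
    return full
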