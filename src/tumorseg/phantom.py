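"""Synthetic tumor-bearing volumes with ground truth and auto-placed seeds.

The phantom emulates a post-contrast T1-weighted liver volume containing a
roughly ellipsoidal lesion: a bright (or dark) ellipsoid in a homogeneous
background, modulated by a smooth multiplicative inhomogeneity field and
corrupted by additive Gaussian noise.  The ground-truth mask is the exact
rasterized ellipsoid and is independent of the noise level and random seed.

Defaults mimic a contrast-enhancing lesion: background 90, tumor 150,
noise sigma 8, 10% smooth inhomogeneity, an 8-voxel-radius sphere centred in
a 64x64x64 grid at 1 mm isotropic spacing.  One tumor seed is placed at the
lesion center and two background seeds at fixed offsets outside the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import SeedSet, Volume

__all__ = ["PhantomSpec", "make_phantom"]


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_level: float = 90.0
    tumor_level: float = 150.0
    tumor_center: tuple[float, float, float] | None = None  # default: volume center
    tumor_radii: tuple[float, float, float] = (8.0, 8.0, 8.0)  # voxels, semi-axes
    inhomogeneity_amp: float = 0.1
    noise_sigma: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if self.tumor_center is None:
            self.tumor_center = tuple((s - 1) / 2.0 for s in self.shape)
        if any(r <= 0 for r in self.tumor_radii):
            raise ValueError("tumor radii must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for c, r, n in zip(self.tumor_center, self.tumor_radii, self.shape):
            if c - r <= 0 or c + r >= n - 1:
                raise ValueError(
                    f"tumor (center {self.tumor_center}, radii {self.tumor_radii}) "
                    f"touches the volume boundary of shape {self.shape}"
                )


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    x, y, z = np.ogrid[: spec.shape[0], : spec.shape[1], : spec.shape[2]]
    cx, cy, cz = spec.tumor_center
    rx, ry, rz = spec.tumor_radii
    q = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    return (q <= 1.0).astype(np.uint8)


def _smooth_field(shape, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency field on [-1, 1]: upsampled coarse noise."""
    coarse = rng.standard_normal((4, 4, 4))
    zoom = [n / 4 for n in shape]
    f = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    f = f[: shape[0], : shape[1], : shape[2]]
    m = np.abs(f).max()
    return f / m if m > 0 else f


def _place_seeds(spec: PhantomSpec, mask: np.ndarray) -> SeedSet:
    center = tuple(int(round(c)) for c in spec.tumor_center)
    gap = 4  # voxels outside the lesion surface
    candidates = []
    for axis, sign in ((0, +1), (1, -1), (2, +1), (0, -1)):
        s = list(center)
        s[axis] += sign * (int(np.ceil(spec.tumor_radii[axis])) + gap)
        if 0 <= s[axis] < spec.shape[axis] and not mask[tuple(s)]:
            candidates.append(tuple(s))
        if len(candidates) == 2:
            break
    if len(candidates) < 2:
        raise ValueError("could not place two background seeds outside the lesion")
    return SeedSet(tumor=[center], background=candidates)


def make_phantom(spec: PhantomSpec | None = None) -> tuple[Volume, np.ndarray, SeedSet]:
    """Build (volume, ground-truth mask, seeds) from a phantom spec.

    Fully reproducible from ``spec.rng_seed``; the mask depends only on the
    geometry, never on the noise draw.
    """
    if spec is None:
        spec = PhantomSpec()
    mask = _ellipsoid_mask(spec)
    img = np.where(mask > 0, spec.tumor_level, spec.background_level).astype(np.float64)
    rng = np.random.default_rng(spec.rng_seed)
    if spec.inhomogeneity_amp != 0:
        img *= 1.0 + spec.inhomogeneity_amp * _smooth_field(spec.shape, rng)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    seeds = _place_seeds(spec, mask)
    return Volume(img, spec.spacing), mask, seeds
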