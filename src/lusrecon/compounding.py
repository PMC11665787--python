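"""Freehand 3D ultrasound compounding.

Tracked (optionally pressure-compensated) B-mode frames are scattered into
a voxel grid aligned with the optical-tracker frame: each pixel lands in
its nearest voxel, overlapping contributions are fused by running mean
(pixel-nearest-neighbor compounding), and remaining empty voxels inside
the swept region are filled from the mean of filled neighbors within a
spherical radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import convolve

from .errors import ValidationError
from .frame import UltrasoundFrame
from .geometry import RigidTransform, pixel_to_world, transform_points

__all__ = ["VoxelVolume", "compound_sweep", "fill_holes"]


@dataclass
class VoxelVolume:
    """Scalar voxel grid in the tracker frame O.

    ``values[ix, iy, iz]`` is the intensity of the voxel centered at
    ``origin + spacing * (ix, iy, iz)``; ``counts`` holds the number of
    scattered pixel contributions; ``hole_filled`` marks voxels filled by
    neighborhood interpolation rather than direct contributions.
    """

    values: np.ndarray
    counts: np.ndarray
    origin: np.ndarray  # mm, frame O
    spacing: float  # mm, isotropic
    hole_filled: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValidationError("voxel spacing must be positive")
        if self.values.shape != self.counts.shape:
            raise ValidationError("values and counts must share a shape")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.hole_filled is None:
            self.hole_filled = np.zeros(self.values.shape, dtype=bool)

    @property
    def shape(self):
        return self.values.shape

    @property
    def filled(self) -> np.ndarray:
        return (self.counts > 0) | self.hole_filled

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing


def compound_sweep(
    frames: Sequence[UltrasoundFrame],
    spacing: float = 0.5,
    margin_mm: float = 0.0,
) -> VoxelVolume:
    """Compound posed frames into a voxel volume (pixel-nearest-neighbor).

    The grid bounding box covers all transformed pixel footprints (pixel
    centers padded by half a pixel, plus ``margin_mm``); each pixel is
    accumulated into its nearest voxel and voxel values are the mean of
    their contributions.
    """
    if len(frames) == 0:
        raise ValidationError("cannot compound an empty frame list")
    if spacing <= 0:
        raise ValidationError("voxel spacing must be positive")

    world = []
    vals = []
    for fr in frames:
        if fr.pose is None:
            raise ValidationError("all frames must carry a pose in frame O")
        pts_f = pixel_to_world(fr)
        intens_f = fr.image.ravel()
        if fr.valid_mask is not None:
            keep = fr.valid_mask.ravel()
            pts_f, intens_f = pts_f[keep], intens_f[keep]
        world.append(pts_f)
        vals.append(intens_f)
    pts = np.concatenate(world)
    intens = np.concatenate(vals)
    if len(pts) == 0:
        raise ValidationError("no valid pixels to compound")

    # grid of voxel centers anchored on the point-cloud minimum; voxel
    # extents (+- spacing/2) cover the transformed pixel footprints
    lo = pts.min(axis=0) - margin_mm
    hi = pts.max(axis=0) + margin_mm
    if not np.all(np.isfinite(hi - lo)):
        raise ValidationError("degenerate bounding box")
    dims = np.maximum(np.floor((hi - lo) / spacing + 0.5).astype(int) + 1, 1)

    idx = np.floor((pts - lo) / spacing + 0.5).astype(int)
    np.clip(idx, 0, dims - 1, out=idx)
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), dims)
    n = int(np.prod(dims))
    sums = np.bincount(flat, weights=intens, minlength=n)
    counts = np.bincount(flat, minlength=n)
    values = np.zeros(n)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    return VoxelVolume(
        values=values.reshape(tuple(dims)),
        counts=counts.reshape(tuple(dims)),
        origin=lo,
        spacing=float(spacing),
    )


def _ball_footprint(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox + 1e-9))
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (xx**2 + yy**2 + zz**2) <= radius_vox**2 + 1e-9


def fill_holes(vol: VoxelVolume, radius_mm: float) -> VoxelVolume:
    """Fill empty voxels from the mean of filled voxels within ``radius_mm``.

    Voxels with no filled neighbor in that radius stay empty; filled and
    previously hole-filled voxels are untouched.
    """
    if radius_mm < vol.spacing:
        raise ValidationError("fill radius must be at least one voxel spacing")
    filled = vol.filled
    if filled.all():
        return VoxelVolume(
            values=vol.values.copy(),
            counts=vol.counts.copy(),
            origin=vol.origin.copy(),
            spacing=vol.spacing,
            hole_filled=vol.hole_filled.copy(),
        )
    foot = _ball_footprint(radius_mm / vol.spacing).astype(float)
    fmask = filled.astype(float)
    neigh_sum = convolve(vol.values * fmask, foot, mode="constant", cval=0.0)
    neigh_cnt = convolve(fmask, foot, mode="constant", cval=0.0)
    values = vol.values.copy()
    hole_filled = vol.hole_filled.copy()
    target = (~filled) & (neigh_cnt > 0.5)
    values[target] = neigh_sum[target] / neigh_cnt[target]
    hole_filled |= target
    return VoxelVolume(
        values=values,
        counts=vol.counts.copy(),
        origin=vol.origin.copy(),
        spacing=vol.spacing,
        hole_filled=hole_filled,
    )
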