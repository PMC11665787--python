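"""Virtual-camera rendering of segmented structures and image augmentation.

Structures segmented from the compounded ultrasound volume are rendered
from a virtual pinhole camera whose intrinsics match the laparoscope and
whose pose follows the tracked laparoscope images; the rendering is
alpha-blended onto the corresponding laparoscope frame, producing
augmented views in which the internal vasculature appears at its tracked
location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.ndimage import binary_erosion

from .errors import ValidationError
from .geometry import CameraIntrinsics, RigidTransform, invert, transform_points

__all__ = [
    "SegmentationVolume",
    "VirtualCamera",
    "DEFAULT_LABEL_COLORS",
    "render_segmentation",
    "overlay_blend",
]

# opaque vessel-like defaults: label -> RGBA in [0, 1]
DEFAULT_LABEL_COLORS: Dict[int, Tuple[float, float, float, float]] = {
    1: (0.85, 0.10, 0.10, 1.0),
    2: (0.10, 0.35, 0.85, 1.0),
    3: (0.95, 0.75, 0.10, 1.0),
    4: (0.10, 0.75, 0.35, 1.0),
}


@dataclass
class SegmentationVolume:
    """Integer label grid with geometry metadata in the tracker frame O."""

    labels: np.ndarray  # (nx, ny, nz) small ints, 0 = background
    origin: np.ndarray  # mm
    spacing: float  # mm, isotropic
    label_names: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValidationError("segmentation spacing must be positive")
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("segmentation labels must be a 3-D grid")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def present_labels(self):
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


@dataclass(frozen=True)
class VirtualCamera:
    """Pinhole camera matching the laparoscope: intrinsics + pose I -> O."""

    intrinsics: CameraIntrinsics
    pose: RigidTransform  # camera/image frame I -> tracker frame O


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    if mask.sum() == 0:
        return np.zeros((0, 3), dtype=int)
    interior = binary_erosion(mask)
    return np.argwhere(mask & ~interior)


def render_segmentation(
    cam: VirtualCamera,
    seg: SegmentationVolume,
    colors: Optional[Dict[int, Tuple[float, float, float, float]]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render the segmentation from the virtual camera.

    Boundary voxels of each label are projected through the pinhole model
    and splatted with a z-buffer (splat radius = projected voxel
    footprint).  Returns an RGBA float image in [0, 1] (fully transparent
    where no structure projects) and a depth map in mm (+inf where empty).
    """
    if colors is None:
        colors = DEFAULT_LABEL_COLORS
    intr = cam.intrinsics
    h, w = intr.height, intr.width
    rgba = np.zeros((h, w, 4), dtype=float)
    depth = np.full((h, w), np.inf)

    world_to_cam = invert(cam.pose)
    vox_all = []
    lab_all = []
    for label in seg.present_labels:
        vox = _boundary_voxels(seg.labels == label)
        vox_all.append(vox)
        lab_all.append(np.full(len(vox), label))
    if not vox_all or sum(len(v) for v in vox_all) == 0:
        return rgba, depth
    vox = np.vstack(vox_all)
    labs = np.concatenate(lab_all)
    pts_o = seg.origin + vox * seg.spacing
    pts_c = transform_points(world_to_cam, pts_o)
    z = pts_c[:, 2]
    front = z > 1e-6
    pts_c, labs, z = pts_c[front], labs[front], z[front]
    if len(z) == 0:
        return rgba, depth
    u = intr.fx * pts_c[:, 0] / z + intr.cx
    v = intr.fy * pts_c[:, 1] / z + intr.cy
    # painter's algorithm: draw far to near so nearer splats overwrite
    order = np.argsort(-z)
    focal = 0.5 * (intr.fx + intr.fy)
    for i in order:
        r_px = max(0.5 * focal * seg.spacing / z[i], 0.5)
        u0, v0 = u[i], v[i]
        c0 = int(np.floor(u0 - r_px))
        c1 = int(np.ceil(u0 + r_px))
        r0 = int(np.floor(v0 - r_px))
        r1 = int(np.ceil(v0 + r_px))
        if c1 < 0 or r1 < 0 or c0 >= w or r0 >= h:
            continue
        c0, c1 = max(c0, 0), min(c1, w - 1)
        r0, r1 = max(r0, 0), min(r1, h - 1)
        cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        inside = (cc - u0) ** 2 + (rr - v0) ** 2 <= r_px**2 + 0.25
        if not inside.any():
            continue
        color = colors.get(int(labs[i]), (1.0, 1.0, 1.0, 1.0))
        rr_in, cc_in = rr[inside], cc[inside]
        closer = z[i] < depth[rr_in, cc_in]
        rr_in, cc_in = rr_in[closer], cc_in[closer]
        depth[rr_in, cc_in] = z[i]
        rgba[rr_in, cc_in, :] = color
    return rgba, depth


def overlay_blend(base: np.ndarray, render: np.ndarray, alpha: float) -> np.ndarray:
    """Blend an RGBA rendering onto an RGB base image.

    Per pixel: out = (1 - alpha * a) * base + alpha * a * render_rgb,
    where ``a`` is the render's alpha channel; the base is unchanged where
    the rendering is transparent.
    """
    base = np.asarray(base, dtype=float)
    render = np.asarray(render, dtype=float)
    if base.ndim != 3 or base.shape[2] != 3:
        raise ValidationError("base must be an H x W x 3 RGB image")
    if render.shape[:2] != base.shape[:2] or render.shape[2] != 4:
        raise ValidationError("render must be RGBA with the base image size")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    a = alpha * render[:, :, 3:4]
    return (1.0 - a) * base + a * render[:, :, :3]
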