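"""Rigid-body poses, the tracking transformation chain, and pose estimation.

Tracked ultrasound reconstruction hinges on expressing every ultrasound
pixel in the common optical-tracker frame ``O``.  The probe tip cannot be
tracked optically inside the abdomen, so its pose is recovered from a
printed keypoint pattern ``P`` seen by the laparoscope camera: the full
chain is

    T_U->O = T_L->O . T_I->L . T_P->I . T_U->P

where ``L`` is the tracked laparoscope body, ``I`` its camera/image frame
(related by hand-eye calibration), ``P`` the probe-tip pattern and ``U``
the ultrasound image frame.  This module provides the pose container, the
labeled chain composition, the ultrasound pixel-to-world map, and a
perspective-n-point solver recovering ``T_P->I`` from detected pattern
keypoints.

All lengths are millimetres; poses are 4x4 row-major homogeneous matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    ChainIncompatibilityError,
    DegenerateGeometryError,
    InsufficientCorrespondencesError,
    ValidationError,
)

_ORTHO_TOL = 1e-6


def _nearest_rotation(m: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix onto SO(3) (orthogonal Procrustes)."""
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        r = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return r


@dataclass(frozen=True)
class RigidTransform:
    """A rigid map between two labeled coordinate frames.

    ``matrix`` is 4x4 homogeneous with an orthonormal, det +1 rotation
    block and translation in mm; it maps points expressed in
    ``from_frame`` into ``to_frame``.
    """

    matrix: np.ndarray
    from_frame: str = ""
    to_frame: str = ""

    def __post_init__(self):
        m = np.array(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError("pose matrix must be 4x4")
        if not np.all(np.isfinite(m)):
            raise ValidationError("pose matrix contains non-finite entries")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            if np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
                m[3] = (0.0, 0.0, 0.0, 1.0)
            else:
                raise ValidationError("last row of a rigid transform must be [0,0,0,1]")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_ORTHO_TOL):
            raise ValidationError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValidationError("rotation block must have determinant +1")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls, from_frame: str = "", to_frame: str = "") -> "RigidTransform":
        return cls(np.eye(4), from_frame, to_frame)

    @classmethod
    def from_rotation_translation(
        cls,
        rotation: np.ndarray,
        translation: Sequence[float],
        from_frame: str = "",
        to_frame: str = "",
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m, from_frame, to_frame)

    # -- accessors ----------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        return transform_points(self, points)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose_chain([self, other])


def compose_chain(chain: Sequence[RigidTransform]) -> RigidTransform:
    """Compose a labeled chain, e.g. [T_L->O, T_I->L, T_P->I, T_U->P] -> T_U->O.

    Adjacent labels must be compatible: the ``from_frame`` of element k
    must equal the ``to_frame`` of element k+1 (matrix product order).
    Empty labels match anything (untracked plumbing transforms).
    """
    if len(chain) == 0:
        raise ValidationError("cannot compose an empty chain")
    for k in range(len(chain) - 1):
        left, right = chain[k], chain[k + 1]
        if left.from_frame and right.to_frame and left.from_frame != right.to_frame:
            raise ChainIncompatibilityError(left.from_frame, right.to_frame, k)
    m = np.eye(4)
    for t in chain:
        m = m @ t.matrix
    m[3] = (0.0, 0.0, 0.0, 1.0)
    return RigidTransform(m, from_frame=chain[-1].from_frame, to_frame=chain[0].to_frame)


def invert(t: RigidTransform) -> RigidTransform:
    r = t.rotation.T
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = -r @ t.translation
    return RigidTransform(m, from_frame=t.to_frame, to_frame=t.from_frame)


def transform_points(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Apply the rigid map to an N x 3 array of points (mm)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValidationError("points must be N x 3")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points contain non-finite coordinates")
    out = pts @ t.rotation.T + t.translation
    return out[0] if single else out


def pixel_to_world(frame, pixels: Optional[np.ndarray] = None) -> np.ndarray:
    """Map ultrasound pixel centers to the tracker frame O.

    A pixel (col, row) lies at (x = col * lateral_spacing,
    y = row * axial_spacing + row0_offset, z = 0) in the image frame ``U``
    (row 0 = transducer face, rows increase with depth), then goes through
    the frame's pose T_U->O.  ``pixels`` is an N x 2 array of (col, row);
    by default all pixels of the image in row-major order.
    """
    if frame.pose is None:
        raise ValidationError("frame has no pose")
    if frame.axial_spacing_mm <= 0 or frame.lateral_spacing_mm <= 0:
        raise ValidationError("frame has no valid pixel spacing")
    if pixels is None:
        rows, cols = np.mgrid[0 : frame.height, 0 : frame.width]
        pixels = np.column_stack([cols.ravel(), rows.ravel()])
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    pts_u = np.zeros((len(pixels), 3))
    pts_u[:, 0] = pixels[:, 0] * frame.lateral_spacing_mm
    pts_u[:, 1] = pixels[:, 1] * frame.axial_spacing_mm + frame.row0_offset_mm
    return transform_points(frame.pose, pts_u)


# ---------------------------------------------------------------------
# Camera model and pattern pose estimation
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of the laparoscope camera (px units)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    distortion: tuple = ()

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValidationError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValidationError("principal point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.fx, 0, self.cx], [0, self.fy, self.cy], [0, 0, 1.0]])


@dataclass(frozen=True)
class PatternGeometry:
    """Ordered 3D keypoints (mm) of the printed probe-tip pattern, frame P."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
            raise ValidationError("pattern needs at least 4 3-D keypoints")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("pattern keypoints must be finite")
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise DegenerateGeometryError("pattern keypoints are collinear")
        pts.flags.writeable = False
        object.__setattr__(self, "points", pts)

    @property
    def is_planar(self) -> bool:
        centered = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        return s[2] < 1e-8 * max(s[0], 1.0)


def project_points(
    intr: CameraIntrinsics, pose: RigidTransform, points: np.ndarray
) -> np.ndarray:
    """Pinhole projection of 3D points (frame of ``pose`` source) to pixels."""
    cam = transform_points(pose, points)
    z = cam[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = intr.fx * cam[:, 0] / z + intr.cx
        v = intr.fy * cam[:, 1] / z + intr.cy
    return np.column_stack([u, v])


def undistort_points(intr: CameraIntrinsics, pixels: np.ndarray) -> np.ndarray:
    """Remove radial distortion (k1, k2, ...) by fixed-point iteration."""
    if not intr.distortion:
        return np.asarray(pixels, dtype=float).copy()
    pts = np.atleast_2d(np.asarray(pixels, dtype=float))
    x = (pts[:, 0] - intr.cx) / intr.fx
    y = (pts[:, 1] - intr.cy) / intr.fy
    xu, yu = x.copy(), y.copy()
    ks = intr.distortion
    for _ in range(20):
        r2 = xu**2 + yu**2
        factor = 1.0
        rpow = r2
        for k in ks:
            factor = factor + k * rpow
            rpow = rpow * r2
        xu, yu = x / factor, y / factor
    return np.column_stack([xu * intr.fx + intr.cx, yu * intr.fy + intr.cy])


@dataclass(frozen=True)
class PnPResult:
    """Pose ``T_P->I`` with its RMS reprojection residual attached."""

    pose: RigidTransform
    residual_px: float
    n_points: int

    @property
    def matrix(self) -> np.ndarray:
        return self.pose.matrix


def _dlt_pose(intr, obj, img):
    """Direct linear transform for >= 6 non-coplanar correspondences."""
    n = len(obj)
    xn = (img[:, 0] - intr.cx) / intr.fx
    yn = (img[:, 1] - intr.cy) / intr.fy
    a = np.zeros((2 * n, 12))
    for i in range(n):
        X = np.append(obj[i], 1.0)
        a[2 * i, 0:4] = X
        a[2 * i, 8:12] = -xn[i] * X
        a[2 * i + 1, 4:8] = X
        a[2 * i + 1, 8:12] = -yn[i] * X
    _, _, vt = np.linalg.svd(a)
    p = vt[-1].reshape(3, 4)
    scale = np.linalg.norm(p[2, :3])
    if scale < 1e-12:
        raise DegenerateGeometryError("DLT produced a degenerate projection")
    p = p / scale
    # positive depth for the centroid
    if (p[2, :3] @ obj.mean(axis=0) + p[2, 3]) < 0:
        p = -p
    r = _nearest_rotation(p[:, :3])
    t = p[:, 3]
    return r, t


def _plane_basis(obj):
    c = obj.mean(axis=0)
    u, s, vt = np.linalg.svd(obj - c)
    e = vt.T  # columns: in-plane x, y, normal
    if np.linalg.det(e) < 0:
        e[:, 2] = -e[:, 2]
    return c, e


def _homography_pose(intr, obj, img):
    """Planar pose init via homography decomposition (any pattern plane)."""
    c, e = _plane_basis(obj)
    q = (obj - c) @ e  # plane coordinates, q[:,2] ~ 0
    xn = (img[:, 0] - intr.cx) / intr.fx
    yn = (img[:, 1] - intr.cy) / intr.fy
    n = len(obj)
    a = np.zeros((2 * n, 9))
    for i in range(n):
        X = np.array([q[i, 0], q[i, 1], 1.0])
        a[2 * i, 0:3] = X
        a[2 * i, 6:9] = -xn[i] * X
        a[2 * i + 1, 3:6] = X
        a[2 * i + 1, 6:9] = -yn[i] * X
    _, _, vt = np.linalg.svd(a)
    h = vt[-1].reshape(3, 3)
    candidates = []
    for sign in (1.0, -1.0):
        hh = sign * h
        lam = 2.0 / (np.linalg.norm(hh[:, 0]) + np.linalg.norm(hh[:, 1]))
        r1 = hh[:, 0] * lam
        r2 = hh[:, 1] * lam
        r3 = np.cross(r1, r2)
        rp = _nearest_rotation(np.column_stack([r1, r2, r3]))
        tp = hh[:, 2] * lam
        # plane frame -> pattern frame
        r = rp @ e.T
        t = tp - r @ c
        candidates.append((r, t))
    return candidates


def pose_from_keypoints(
    intr: CameraIntrinsics,
    pattern: PatternGeometry,
    detections: np.ndarray,
) -> PnPResult:
    """Estimate the pattern pose T_P->I from detected 2D keypoints.

    Correspondences are by index: ``detections[i]`` is the (undistorted)
    pixel location of ``pattern.points[i]``.  The pose minimizing the mean
    squared reprojection error is found by nonlinear least squares,
    initialized by a direct linear method (DLT for non-coplanar patterns,
    homography decomposition for planar ones); pose ambiguities are
    resolved by lowest residual, then by all points having positive depth.
    """
    det = np.atleast_2d(np.asarray(detections, dtype=float))
    obj = pattern.points
    if len(det) < 4:
        raise InsufficientCorrespondencesError(
            f"need at least 4 correspondences, got {len(det)}"
        )
    if len(det) != len(obj):
        raise ValidationError("detections must match pattern keypoints by index")
    if not np.all(np.isfinite(det)):
        raise ValidationError("detections contain non-finite coordinates")

    inits = []
    if pattern.is_planar:
        inits.extend(_homography_pose(intr, obj, det))
    elif len(obj) >= 6:
        try:
            inits.append(_dlt_pose(intr, obj, det))
        except DegenerateGeometryError:
            pass
    if not inits:
        # fallback starts: identity-ish rotations at a scale-derived distance
        span_obj = np.ptp(obj, axis=0).max()
        span_img = max(np.ptp(det, axis=0).max(), 1.0)
        z0 = intr.fx * span_obj / span_img
        for rot in (np.eye(3), Rotation.from_euler("x", 180, degrees=True).as_matrix()):
            inits.append((rot, np.array([0.0, 0.0, z0]) - rot @ obj.mean(axis=0)))

    def residuals(x):
        r = Rotation.from_rotvec(x[:3]).as_matrix()
        cam = obj @ r.T + x[3:]
        z = np.where(np.abs(cam[:, 2]) < 1e-9, 1e-9, cam[:, 2])
        u = intr.fx * cam[:, 0] / z + intr.cx
        v = intr.fy * cam[:, 1] / z + intr.cy
        return np.concatenate([u - det[:, 0], v - det[:, 1]])

    best = None
    for r0, t0 in inits:
        x0 = np.concatenate([Rotation.from_matrix(r0).as_rotvec(), t0])
        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
        r = Rotation.from_rotvec(sol.x[:3]).as_matrix()
        t = sol.x[3:]
        depths = (obj @ r.T + t)[:, 2]
        front = bool(np.all(depths > 0))
        key = (sol.cost, not front)
        if best is None or key < best[0]:
            best = (key, r, t, sol.cost)
    _, r, t, cost = best
    rms = float(np.sqrt(2.0 * cost / (2 * len(det))))
    pose = RigidTransform.from_rotation_translation(r, t, from_frame="P", to_frame="I")
    return PnPResult(pose=pose, residual_px=rms, n_points=len(det))
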