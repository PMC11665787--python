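"""Probe-pressure deformation estimation and compensation.

During acquisition the ultrasound transducer indents the liver.  Content
in the B-mode image is therefore displaced toward the probe relative to
the organ's rest shape, most strongly at the surface and negligibly below
a *stress decay depth* ``c``.  The axial displacement applied to undo the
deformation is modeled, per image column, as

    dz(z) = d * exp(-z / (c - z))   for 0 <= z < c,      dz(z) = 0 for z >= c

where ``d`` (mm) is the indentation of that column: the vertical distance
between the probe-tissue contact line (image row 0 mapped to tracker
space) and a reference liver surface fitted by least squares to surface
sample points.  ``c`` (mm) is estimated per frame pair by matching
features between consecutive frames and finding the decay depths that
make the de-shifted feature depths agree:

    min_{c0,c1} sum_k [ (p0k - d0k e^{-p0k/(c0-p0k)}) - (p1k - d1k e^{-p1k/(c1-p1k)}) ]^2

The compensation warp z -> z - dz(z) is strictly increasing for d >= 0
and c > 0, hence invertible; frames are resampled through its numerical
inverse onto a canvas extended above the transducer face so the restored
surface content is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import EuclideanTransform

from .errors import (
    DegenerateGeometryError,
    DomainError,
    InsufficientMatchesError,
    ValidationError,
)
from .frame import UltrasoundFrame
from .geometry import pixel_to_world

__all__ = [
    "ReferenceSurface",
    "ContactLine",
    "DisplacementProfile",
    "DecayEstimate",
    "FeatureMatchSet",
    "fit_reference_surface",
    "extract_contact_line",
    "compute_displacement_profile",
    "displacement_at_columns",
    "decay_shift",
    "compensate_frame",
    "match_features",
    "estimate_decay_depths",
]


# ---------------------------------------------------------------------
# Reference surface
# ---------------------------------------------------------------------


def _poly_terms(order: int):
    return [(i, j) for total in range(order + 1) for i in range(total + 1) for j in [total - i]]


def _design_matrix(xy: np.ndarray, order: int) -> np.ndarray:
    terms = _poly_terms(order)
    return np.column_stack([xy[:, 0] ** i * xy[:, 1] ** j for i, j in terms])


@dataclass(frozen=True)
class ReferenceSurface:
    """Least-squares height surface h = f(a, b) over a lateral rectangle.

    The surface lives in a gravity-aligned working frame: ``height_axis``
    names the tracker-frame axis along which depth increases (gravity
    direction); the other two axes, in ascending index order, are the
    lateral coordinates (a, b).  ``coefficients`` are those of a bivariate
    polynomial of total degree ``order``, terms in graded order
    (1, b, a, b^2, ab, a^2, ...).
    """

    order: int
    coefficients: np.ndarray
    domain: Tuple[Tuple[float, float], Tuple[float, float]]
    residual_rms_mm: float
    height_axis: int = 2

    @property
    def lateral_axes(self) -> Tuple[int, int]:
        axes = [a for a in range(3) if a != self.height_axis]
        return axes[0], axes[1]

    def evaluate(self, lateral: np.ndarray) -> np.ndarray:
        """Surface height at N x 2 lateral coordinates (mm)."""
        xy = np.atleast_2d(np.asarray(lateral, dtype=float))
        return _design_matrix(xy, self.order) @ self.coefficients

    def contains(self, lateral: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(lateral, dtype=float))
        (a0, a1), (b0, b1) = self.domain
        return (xy[:, 0] >= a0) & (xy[:, 0] <= a1) & (xy[:, 1] >= b0) & (xy[:, 1] <= b1)

    def clamp(self, lateral: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(lateral, dtype=float)).copy()
        (a0, a1), (b0, b1) = self.domain
        xy[:, 0] = np.clip(xy[:, 0], a0, a1)
        xy[:, 1] = np.clip(xy[:, 1], b0, b1)
        return xy


def fit_reference_surface(
    samples: np.ndarray, model_order: int = 2, height_axis: int = 2
) -> ReferenceSurface:
    """Fit the reference (rest-shape) liver surface to 3D sample points.

    ``samples`` is M x 3 (mm, tracker frame); the fit is linear least
    squares of the height coordinate on a bivariate polynomial of the
    lateral coordinates.
    """
    pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("surface samples must be M x 3")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("surface samples must be finite")
    terms = _poly_terms(model_order)
    if len(pts) < len(terms):
        raise ValidationError(
            f"need at least {len(terms)} samples for an order-{model_order} surface"
        )
    lat_axes = [a for a in range(3) if a != height_axis]
    xy = pts[:, lat_axes]
    h = pts[:, height_axis]
    a = _design_matrix(xy, model_order)
    coef, _, rank, _ = np.linalg.lstsq(a, h, rcond=None)
    if rank < len(terms):
        raise DegenerateGeometryError(
            "surface samples are degenerate (rank-deficient design matrix)"
        )
    resid = a @ coef - h
    rms = float(np.sqrt(np.mean(resid**2)))
    domain = (
        (float(xy[:, 0].min()), float(xy[:, 0].max())),
        (float(xy[:, 1].min()), float(xy[:, 1].max())),
    )
    return ReferenceSurface(
        order=model_order,
        coefficients=coef,
        domain=domain,
        residual_rms_mm=rms,
        height_axis=height_axis,
    )


# ---------------------------------------------------------------------
# Contact line and displacement profile
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ContactLine:
    """World coordinates (mm, frame O) of image row 0 — the probe-tissue interface."""

    points: np.ndarray  # W x 3
    valid: np.ndarray  # W bool
    frame_id: int = 0


def extract_contact_line(frame: UltrasoundFrame) -> ContactLine:
    """The liver surface as seen by the probe: row 0 of the image in frame O."""
    if frame.pose is None:
        raise ValidationError("frame has no pose")
    cols = np.arange(frame.width)
    pixels = np.column_stack([cols, np.zeros_like(cols)])
    pts = pixel_to_world(frame, pixels)
    return ContactLine(points=pts, valid=np.ones(frame.width, bool), frame_id=frame.frame_id)


@dataclass(frozen=True)
class DisplacementProfile:
    """Per-column surface displacement d (mm), clamped at zero where the
    contact line lies above the reference surface."""

    d: np.ndarray  # W, mm, >= 0
    clamped: np.ndarray  # W bool: raw displacement was negative
    valid: np.ndarray  # W bool: column footprint inside the surface domain
    frame_id: int = 0

    def mean_valid(self) -> float:
        if not self.valid.any():
            return 0.0
        return float(self.d[self.valid].mean())


def compute_displacement_profile(
    line: ContactLine, surface: ReferenceSurface
) -> DisplacementProfile:
    """Vertical distance from each contact-line point down from the reference surface.

    Per column, d = (contact height) - (surface height at the contact
    point's lateral coordinates), measured along the gravity axis and
    clamped at 0 when the contact line lies above the surface.  Columns
    whose lateral footprint falls outside the fitted domain are evaluated
    at the clamped location and flagged invalid.
    """
    lat = line.points[:, list(surface.lateral_axes)]
    inside = surface.contains(lat)
    if not inside.any():
        raise DomainError("contact line lies entirely outside the surface domain")
    heights = surface.evaluate(surface.clamp(lat))
    d_raw = line.points[:, surface.height_axis] - heights
    clamped = d_raw < 0
    d = np.clip(d_raw, 0.0, None)
    return DisplacementProfile(
        d=d, clamped=clamped, valid=line.valid & inside, frame_id=line.frame_id
    )


def displacement_at_columns(profile: DisplacementProfile, cols: np.ndarray) -> np.ndarray:
    """d evaluated at (possibly fractional) column indices; invalid columns
    fall back to the frame's mean valid displacement."""
    cols = np.asarray(cols, dtype=float)
    idx = np.clip(np.round(cols).astype(int), 0, len(profile.d) - 1)
    d = profile.d[idx].astype(float)
    bad = ~profile.valid[idx]
    d[bad] = profile.mean_valid()
    return d


# ---------------------------------------------------------------------
# The decay model
# ---------------------------------------------------------------------


def decay_shift(z, d, c):
    """Axial compensation shift dz(z) = d * exp(-z/(c-z)) for z < c, else 0.

    ``z`` is depth below the transducer face (mm), ``d`` the surface
    displacement (mm), ``c`` the stress decay depth (mm).  Inputs
    broadcast; negative z or d, or non-positive c, are rejected.
    """
    z = np.asarray(z, dtype=float)
    d_arr = np.asarray(d, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    if np.any(z < 0):
        raise ValidationError("depth z must be non-negative")
    if np.any(d_arr < 0):
        raise ValidationError("displacement d must be non-negative")
    if np.any(c_arr <= 0):
        raise ValidationError("decay depth c must be positive")
    z, d_arr, c_arr = np.broadcast_arrays(z, d_arr, c_arr)
    out = np.zeros(z.shape, dtype=float)
    m = z < c_arr
    out[m] = d_arr[m] * np.exp(-z[m] / (c_arr[m] - z[m]))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class DecayEstimate:
    """Estimated stress decay depth for one frame."""

    c_mm: float
    frame_ids: Tuple[int, int] = (-1, -1)
    converged: bool = False
    objective: float = float("inf")
    n_matches: int = 0

    def __post_init__(self):
        if self.c_mm <= 0:
            raise ValidationError("decay depth must be positive")


# ---------------------------------------------------------------------
# Frame compensation
# ---------------------------------------------------------------------


def compensate_frame(
    frame: UltrasoundFrame,
    profile: DisplacementProfile,
    decay: DecayEstimate,
) -> UltrasoundFrame:
    """Warp a frame axially to undo probe-pressure deformation.

    Per column, content at depth z moves to z' = z - dz(z, d_col, c); the
    output is resampled on the original axial grid extended upward
    (negative depth) by max(d) so that surface content restored above the
    transducer face is retained.  The pose is unchanged;
    ``row0_offset_mm`` records the new axial origin of row 0.
    """
    if len(profile.d) != frame.width:
        raise ValidationError("displacement profile width does not match the image")
    if frame.row0_offset_mm != 0.0:
        raise ValidationError("frame was already compensated (row0 offset non-zero)")
    s_ax = frame.axial_spacing_mm
    h, w = frame.image.shape
    d = profile.d.astype(float).copy()
    if (~profile.valid).any():
        d[~profile.valid] = profile.mean_valid()
    c = decay.c_mm
    max_d = float(d.max()) if len(d) else 0.0
    pad = int(math.ceil(max_d / s_ax - 1e-9))
    z_in = np.arange(h) * s_ax
    z_out = (np.arange(h + pad) - pad) * s_ax
    out = np.zeros((h + pad, w), dtype=float)
    valid = np.zeros((h + pad, w), dtype=bool)
    for col in range(w):
        g = z_in - decay_shift(z_in, d[col], c)
        if np.any(np.diff(g) <= 0):  # cannot happen for d >= 0; guards the model
            raise AssertionError("compensation map is not strictly increasing")
        z_src = np.interp(z_out, g, z_in, left=np.nan, right=np.nan)
        vals = np.interp(z_src, z_in, frame.image[:, col])
        good = np.isfinite(z_src)
        vals[~good] = 0.0
        out[:, col] = vals
        if frame.valid_mask is not None:
            # propagate pre-existing invalid pixels through the warp
            src_rows = np.clip(
                np.round(np.nan_to_num(z_src) / s_ax).astype(int), 0, h - 1
            )
            good = good & frame.valid_mask[src_rows, col]
        valid[:, col] = good
    return replace(
        frame,
        image=np.clip(out, 0.0, 1.0),
        row0_offset_mm=-pad * s_ax,
        valid_mask=valid,
    )


# ---------------------------------------------------------------------
# Feature matching between consecutive frames
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureMatchSet:
    """SIFT matches between two consecutive frames with a consensus inlier mask.

    Rows/columns are pixel coordinates in each frame; ``p0_mm``/``p1_mm``
    are the matched feature depths converted to mm by the axial spacing.
    """

    cols0: np.ndarray
    rows0: np.ndarray
    cols1: np.ndarray
    rows1: np.ndarray
    p0_mm: np.ndarray
    p1_mm: np.ndarray
    inliers: np.ndarray  # bool mask over matches
    frame_ids: Tuple[int, int] = (0, 1)

    def __post_init__(self):
        if np.any(self.p0_mm < 0) or np.any(self.p1_mm < 0):
            raise ValidationError("match depths must be non-negative")

    @property
    def n_inliers(self) -> int:
        return int(self.inliers.sum())

    def inlier_arrays(self):
        m = self.inliers
        return (
            self.cols0[m],
            self.p0_mm[m],
            self.cols1[m],
            self.p1_mm[m],
        )


def match_features(
    frame0: UltrasoundFrame,
    frame1: UltrasoundFrame,
    min_inliers: int = 4,
    max_ratio: float = 0.8,
    residual_threshold_px: float = 2.0,
    rng: int = 0,
) -> FeatureMatchSet:
    """SIFT correspondences between consecutive frames, outliers removed by RANSAC.

    The consensus model is a 2D rigid (Euclidean) transform — adequate for
    the small inter-frame motion of a slow sweep.  Raises
    :class:`InsufficientMatchesError` when fewer than ``min_inliers``
    survive; callers fall back (e.g. hold the previous decay estimate).
    """
    if frame0.image.shape != frame1.image.shape:
        raise ValidationError("frames must share the same image geometry")
    if abs(frame0.axial_spacing_mm - frame1.axial_spacing_mm) > 1e-12:
        raise ValidationError("frames must share the axial pixel spacing")

    descriptors = []
    keypoints = []
    for fr in (frame0, frame1):
        ext = SIFT()
        try:
            ext.detect_and_extract(fr.image)
        except RuntimeError as exc:  # no features found
            raise InsufficientMatchesError(str(exc)) from exc
        keypoints.append(ext.keypoints)  # (row, col)
        descriptors.append(ext.descriptors)
    matches = match_descriptors(
        descriptors[0], descriptors[1], cross_check=True, max_ratio=max_ratio
    )
    if len(matches) < min_inliers:
        raise InsufficientMatchesError(
            f"only {len(matches)} putative matches (< {min_inliers})"
        )
    kp0 = keypoints[0][matches[:, 0]].astype(float)
    kp1 = keypoints[1][matches[:, 1]].astype(float)
    inliers = filter_matches_ransac(
        kp0, kp1, residual_threshold_px=residual_threshold_px, rng=rng
    )
    if inliers.sum() < min_inliers:
        raise InsufficientMatchesError(
            f"only {int(inliers.sum())} consensus inliers (< {min_inliers})"
        )
    s_ax = frame0.axial_spacing_mm
    return FeatureMatchSet(
        cols0=kp0[:, 1],
        rows0=kp0[:, 0],
        cols1=kp1[:, 1],
        rows1=kp1[:, 0],
        p0_mm=kp0[:, 0] * s_ax,
        p1_mm=kp1[:, 0] * s_ax,
        inliers=inliers,
        frame_ids=(frame0.frame_id, frame1.frame_id),
    )


def filter_matches_ransac(
    kp0: np.ndarray,
    kp1: np.ndarray,
    residual_threshold_px: float = 2.0,
    rng: int = 0,
) -> np.ndarray:
    """Consensus inlier mask for matched keypoints under a 2D rigid model."""
    if len(kp0) < 3:
        return np.ones(len(kp0), bool)
    # Degenerate (identical) correspondences make the model fit exactly.
    if np.allclose(kp0, kp1):
        return np.ones(len(kp0), bool)
    _, inliers = ransac(
        (kp0, kp1),
        EuclideanTransform,
        min_samples=3,
        residual_threshold=residual_threshold_px,
        max_trials=300,
        rng=rng,
    )
    if inliers is None:
        return np.zeros(len(kp0), bool)
    return np.asarray(inliers, bool)


# ---------------------------------------------------------------------
# Decay-depth estimation
# ---------------------------------------------------------------------


def estimate_decay_depths(
    matches: FeatureMatchSet,
    d0: Union[float, np.ndarray],
    d1: Union[float, np.ndarray],
    bounds: Tuple[float, float],
    imaging_depth_mm: Optional[float] = None,
    face_offset_mm: Union[float, np.ndarray] = 0.0,
    eps_mm: float = 1.0,
    n_starts: int = 3,
) -> Tuple[DecayEstimate, DecayEstimate]:
    """Estimate the stress decay depths (c0, c1) of two consecutive frames.

    ``d0``/``d1`` are the surface displacements of the two frames at the
    matched columns (scalar, or arrays aligned with the inlier matches).
    The estimator minimizes, over the inlier matches, the squared
    disagreement of the de-shifted depths

        [(p0 - d0 e^{-p0/(c0-p0)}) - (p1 - d1 e^{-p1/(c1-p1)}) + offset]

    with c constrained to ``bounds`` and to exceed the deepest match used
    by ``eps_mm``.  The de-shifted depth of a match is its rest depth
    *below that frame's transducer face*; when the two faces sit at
    different heights (they do whenever the indentation differs),
    ``face_offset_mm`` — the face height of frame 0 minus that of frame 1
    along the gravity axis, scalar or per inlier match — restores
    comparability.  The default 0 is exact for frames sharing the face
    height.  The decay shift vanishes identically for matches at or below
    a candidate c (piecewise model), so matches at every depth enter the
    objective: deep matches anchor the de-shifted depths where the
    pressure effect is negligible, shallow ones carry the decay signal.
    On failure (no inlier matches, optimizer breakdown) a fallback
    estimate at ``imaging_depth_mm`` (or the bounds midpoint) is returned
    with ``converged=False``.
    """
    c_min, c_max = float(bounds[0]), float(bounds[1])
    if not (0 < c_min < c_max):
        raise ValidationError("decay bounds must satisfy 0 < c_min < c_max")
    _, p0, _, p1 = matches.inlier_arrays()
    n = len(p0)
    d0a = np.broadcast_to(np.asarray(d0, dtype=float), (n,)).copy()
    d1a = np.broadcast_to(np.asarray(d1, dtype=float), (n,)).copy()
    offs = np.broadcast_to(np.asarray(face_offset_mm, dtype=float), (n,)).copy()
    if np.any(d0a < 0) or np.any(d1a < 0):
        raise ValidationError("surface displacements must be non-negative")

    fallback_c = imaging_depth_mm if imaging_depth_mm is not None else 0.5 * (c_min + c_max)

    p0k, p1k, d0k, d1k, offk = p0, p1, d0a, d1a, offs
    if len(p0k) == 0:
        return (
            DecayEstimate(fallback_c, matches.frame_ids, False, float("inf"), 0),
            DecayEstimate(fallback_c, matches.frame_ids, False, float("inf"), 0),
        )
    lo = c_min

    def _shift(p, d, c):
        # piecewise decay: zero at and below the decay depth
        s = np.zeros_like(p)
        m = p < c - 1e-9
        s[m] = d[m] * np.exp(-p[m] / (c - p[m]))
        return s

    def residuals(x):
        c0, c1 = x
        return (p0k - _shift(p0k, d0k, c0)) - (p1k - _shift(p1k, d1k, c1)) + offk

    mid = 0.5 * (lo + c_max)
    obj_mid = float(np.sum(residuals([mid, mid]) ** 2))
    if obj_mid < 1e-18:
        # Degenerate symmetric case: every admissible c explains the data.
        e = DecayEstimate(mid, matches.frame_ids, True, 0.0, len(p0k))
        return e, e

    best = None
    for f in np.linspace(0.25, 0.75, n_starts):
        x0 = [lo + f * (c_max - lo)] * 2
        sol = least_squares(
            residuals, x0, bounds=([lo, lo], [c_max, c_max]), xtol=1e-12, ftol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best = sol
    converged = bool(best.success)
    objective = float(2.0 * best.cost)
    return (
        DecayEstimate(float(best.x[0]), matches.frame_ids, converged, objective, len(p0k)),
        DecayEstimate(float(best.x[1]), matches.frame_ids, converged, objective, len(p0k)),
    )
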