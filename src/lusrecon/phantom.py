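"""Synthetic ground-truthed phantom acquisitions.

The clinical data this toolkit targets (tracked laparoscopic-ultrasound
sweeps of the liver) cannot be redistributed, so every pipeline stage is
exercised on a fully synthetic phantom: a smooth height-field "liver"
surface over a textured tissue volume containing a branching vessel tree
with analytically known centerlines.  A simulated probe sweep indents the
surface following a per-frame displacement schedule d(t) and decay-depth
schedule c(t); each B-mode frame is sampled from the rest-shape volume
through the forward pressure deformation (the exact inverse of the
compensation warp, so compensating with the true parameters recovers the
undeformed slice), then corrupted with multiplicative speckle, additive
noise, and pose noise.  True poses, per-column displacement profiles and
per-frame decay depths are returned alongside.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial.transform import Rotation

from .errors import GenerationError, TrajectoryError, ValidationError
from .frame import UltrasoundFrame
from .geometry import RigidTransform
from .pressure import decay_shift

__all__ = ["PhantomSpec", "PhantomTruth", "SweepSimulation", "generate_phantom", "simulate_sweep"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters of the synthetic acquisition.

    Defaults describe a liver-like scene at desk scale: a ~50 mm lateral
    field with a gently undulating surface ~5 mm deep, three hypoechoic
    vessels 10-20 mm below the surface, and a 100-frame linear sweep with
    up to ~6 mm of probe indentation.  The tracker frame O has its z axis
    along gravity (increasing downward); the undeformed volume's origin is
    (0, 0, 0) mm in O.
    """

    seed: int = 0

    # rest-shape volume
    volume_spacing: float = 0.5  # mm, isotropic
    extent_mm: Tuple[float, float, float] = (50.0, 55.0, 62.0)
    tissue_intensity: float = 0.35
    tissue_texture_amp: float = 0.06
    air_intensity: float = 0.0
    vessel_intensity: float = 0.04

    # surface z = z0 + ax sin(2 pi x / Px + phx) + ay sin(2 pi y / Py + phy)
    surface_z0: float = 5.0
    surface_amp: Tuple[float, float] = (1.0, 0.8)
    surface_period: Tuple[float, float] = (60.0, 50.0)

    # vessel tree
    vessel_radii: Tuple[float, float, float] = (2.5, 2.0, 1.6)
    vessel_depth_range: Tuple[float, float] = (10.0, 20.0)
    vessel_tortuosity: float = 1.0

    # sweep trajectory / imaging geometry
    n_frames: int = 100
    frame_step_mm: float = 0.5
    image_shape: Tuple[int, int] = (150, 128)  # rows (depth), cols (lateral)
    axial_spacing: float = 0.3  # mm / px
    lateral_spacing: float = 0.3
    probe_x0: float = 6.0
    sweep_y0: float = 2.5
    probe_tilt_deg: float = 0.0  # max tilt about the sweep axis

    # deformation schedules (mm)
    d_base: float = 3.0
    d_amp: float = 2.0
    d_cycles: float = 2.0
    c_base: float = 30.0
    c_amp: float = 8.0
    c_cycles: float = 1.0
    d_jitter_mm: float = 0.6  # frame-to-frame pressure variation (surgeon handling)
    c_jitter_mm: float = 2.0
    model_mismatch: bool = False  # linear decay profile instead of exponential

    # noise
    speckle_strength: float = 0.25
    noise_sigma: float = 0.01
    smooth_sigma: float = 0.6
    pose_noise_rot_deg: float = 0.1
    pose_noise_trans_mm: float = 0.1

    # reference-surface sampling (emulates manual sampling on the scene model)
    surface_sample_grid: Tuple[int, int] = (13, 13)
    surface_sample_noise_mm: float = 0.1

    def __post_init__(self):
        if self.volume_spacing <= 0 or self.axial_spacing <= 0 or self.lateral_spacing <= 0:
            raise ValidationError("spacings must be positive")
        if self.n_frames < 1 or self.frame_step_mm <= 0:
            raise ValidationError("sweep needs at least one frame and a positive step")
        if min(self.vessel_radii) <= 0 or self.vessel_depth_range[0] <= 0:
            raise ValidationError("vessel geometry parameters must be positive")
        if self.c_base - self.c_amp <= 0 or self.d_base - self.d_amp < 0:
            raise ValidationError("deformation schedules must stay non-negative (d) / positive (c)")


@dataclass
class PhantomTruth:
    """Ground truth of one generated phantom."""

    spec: PhantomSpec
    volume: np.ndarray  # rest-shape intensities, (nx, ny, nz); air above the surface
    imaging_volume: np.ndarray  # same grid, tissue continued above the surface
    vessel_mask: np.ndarray  # boolean, same grid
    spacing: float
    origin: np.ndarray  # (0,0,0) mm
    centerlines: List[np.ndarray]  # analytic vessel centerlines, mm
    surface_samples: np.ndarray  # M x 3 noisy samples on the rest surface
    d_schedule: np.ndarray  # per-frame commanded indentation, mm
    c_schedule: np.ndarray  # per-frame decay depth, mm

    def surface_height(self, x, y) -> np.ndarray:
        """Analytic rest-surface height z = f(x, y) (mm, gravity axis z)."""
        s = self.spec
        ax, ay = s.surface_amp
        px, py = s.surface_period
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            s.surface_z0
            + ax * np.sin(2 * np.pi * x / px + self._phase[0])
            + ay * np.sin(2 * np.pi * y / py + self._phase[1])
        )

    _phase: Tuple[float, float] = (0.0, 0.0)


@dataclass
class SweepSimulation:
    """One simulated tracked sweep."""

    frames: List[UltrasoundFrame]  # measured (noise-perturbed) poses
    true_poses: List[RigidTransform]
    true_d_profiles: np.ndarray  # n_frames x width, mm
    true_c: np.ndarray  # n_frames, mm


# ---------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------


def _bezier(p0, p1, p2, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _vessel_centerlines(spec: PhantomSpec, rng: np.random.Generator, phase) -> List[np.ndarray]:
    z0 = spec.surface_z0
    dmin, dmax = spec.vessel_depth_range
    dmid, damp = 0.5 * (dmin + dmax), 0.4 * (dmax - dmin)
    tort = spec.vessel_tortuosity
    ph = rng.uniform(0, 2 * np.pi, size=4)

    t = np.linspace(0.0, 1.0, 220)
    main = np.column_stack(
        [
            9.0 + 31.0 * t + 2.0 * tort * np.sin(2 * np.pi * 1.3 * t + ph[0]),
            4.0 + 46.0 * t,
            z0 + dmid + damp * np.sin(2 * np.pi * 1.1 * t + ph[1]),
        ]
    )
    a = main[int(0.55 * (len(main) - 1))]
    end2 = np.array([14.0, 50.0, z0 + dmax + 2.0])
    ctrl2 = 0.5 * (a + end2) + np.array([2.0 * tort * np.sin(ph[2]), 0.0, -2.0])
    branch2 = _bezier(a, ctrl2, end2, 120)
    b = main[int(0.30 * (len(main) - 1))]
    end3 = np.array([38.0, 12.0, z0 + dmax])
    ctrl3 = 0.5 * (b + end3) + np.array([0.0, 2.0 * tort * np.cos(ph[3]), 3.0])
    branch3 = _bezier(b, ctrl3, end3, 100)
    return [main, branch2, branch3]


def _voxelize_tubes(
    centerlines: List[np.ndarray], radii, shape, spacing: float
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    dims = np.asarray(shape)
    for pts, r0 in zip(centerlines, radii):
        # taper toward the distal end
        n = len(pts)
        radii_t = np.linspace(r0, 0.7 * r0, n)
        # resample densely enough that consecutive stamps overlap
        for p, r in zip(pts, radii_t):
            rv = r / spacing
            ctr = p / spacing
            lo = np.maximum(np.floor(ctr - rv).astype(int), 0)
            hi = np.minimum(np.ceil(ctr + rv).astype(int) + 1, dims)
            if np.any(lo >= hi):
                continue
            xx, yy, zz = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            inside = (xx - ctr[0]) ** 2 + (yy - ctr[1]) ** 2 + (zz - ctr[2]) ** 2 <= rv**2
            mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= inside
    return mask


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate the rest-shape phantom: surface, textured volume, vessels."""
    rng = np.random.default_rng(spec.seed)
    sp = spec.volume_spacing
    shape = tuple(int(round(e / sp)) + 1 for e in spec.extent_mm)
    phase = tuple(rng.uniform(0, 2 * np.pi, size=2))

    centerlines = _vessel_centerlines(spec, rng, phase)
    rmax = max(spec.vessel_radii)
    for pts in centerlines:
        if np.any(pts - rmax < 0) or np.any(pts + rmax > np.asarray(spec.extent_mm)):
            raise GenerationError("vessel tree leaves the phantom volume")

    # tissue texture (smoothed noise around the mean tissue level)
    texture = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    texture = texture / max(texture.std(), 1e-9) * spec.tissue_texture_amp
    volume = np.clip(spec.tissue_intensity + texture, 0.05, 0.95)

    imaging_volume = None  # assigned below, before the air cut
    # air above the surface
    x = np.arange(shape[0]) * sp
    y = np.arange(shape[1]) * sp
    z = np.arange(shape[2]) * sp
    ax, ay = spec.surface_amp
    px, py = spec.surface_period
    f_xy = (
        spec.surface_z0
        + ax * np.sin(2 * np.pi * x[:, None] / px + phase[0])
        + ay * np.sin(2 * np.pi * y[None, :] / py + phase[1])
    )
    air = z[None, None, :] < f_xy[:, :, None]

    vessel_mask = _voxelize_tubes(centerlines, spec.vessel_radii, shape, sp)
    volume[vessel_mask] = spec.vessel_intensity
    # the probe only ever images tissue; keep a boundary-free volume for
    # image synthesis and cut the air out of the reference volume only
    imaging_volume = volume.copy()
    volume = volume.copy()
    volume[air] = spec.air_intensity

    # noisy surface samples (stand-in for manual sampling on a scene model)
    gx, gy = spec.surface_sample_grid
    sx = np.linspace(3.0, spec.extent_mm[0] - 3.0, gx)
    sy = np.linspace(1.0, spec.extent_mm[1] - 1.0, gy)
    xx, yy = np.meshgrid(sx, sy, indexing="ij")
    zz = (
        spec.surface_z0
        + ax * np.sin(2 * np.pi * xx / px + phase[0])
        + ay * np.sin(2 * np.pi * yy / py + phase[1])
    )
    samples = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    samples[:, 2] += rng.normal(0.0, spec.surface_sample_noise_mm, len(samples))

    truth = PhantomTruth(
        spec=spec,
        volume=volume,
        imaging_volume=imaging_volume,
        vessel_mask=vessel_mask,
        spacing=sp,
        origin=np.zeros(3),
        centerlines=centerlines,
        surface_samples=samples,
        d_schedule=_d_schedule(spec, rng),
        c_schedule=_c_schedule(spec, rng),
    )
    truth._phase = phase
    return truth


def _d_schedule(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(spec.n_frames)
    d = spec.d_base + spec.d_amp * np.sin(
        2 * np.pi * spec.d_cycles * t / max(spec.n_frames, 1)
    )
    if spec.d_jitter_mm > 0:
        d = d + rng.normal(0.0, spec.d_jitter_mm, spec.n_frames)
    return np.clip(d, 0.0, None)


def _c_schedule(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(spec.n_frames)
    c = spec.c_base + spec.c_amp * np.sin(
        2 * np.pi * spec.c_cycles * t / max(spec.n_frames, 1) + 1.0
    )
    if spec.c_jitter_mm > 0:
        c = c + rng.normal(0.0, spec.c_jitter_mm, spec.n_frames)
    return np.clip(c, 8.0, None)


# ---------------------------------------------------------------------
# Sweep simulation
# ---------------------------------------------------------------------

# columns are the images of the U basis vectors: lateral -> +x,
# depth -> +z (gravity), out-of-plane -> -y (right-handed, det +1)
_R_BASE = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 0.0, -1.0],
        [0.0, 1.0, 0.0],
    ]
)


def _forward_shift(z, d, c, mismatch: bool):
    if mismatch:
        z = np.asarray(z, dtype=float)
        return d * np.clip(1.0 - z / c, 0.0, None)
    return decay_shift(z, d, c)


def simulate_sweep(truth: PhantomTruth, spec: Optional[PhantomSpec] = None) -> SweepSimulation:
    """Simulate the tracked, pressure-deformed ultrasound sweep.

    Per frame the probe face is placed on the surface indented by d(t);
    each image column is sampled from the rest-shape volume through the
    forward deformation map (content at image depth z originates at rest
    depth z - dz(z)), speckle and additive noise are applied, and the
    returned frame poses carry the spec's pose noise.  True poses, true
    per-column displacement profiles and true decay depths come back
    alongside.
    """
    if spec is None:
        spec = truth.spec
    rng = np.random.default_rng(spec.seed + 1)
    h, w = spec.image_shape
    s_ax, s_lat = spec.axial_spacing, spec.lateral_spacing
    cols = np.arange(w)
    z_rows = np.arange(h) * s_ax

    d_sched = truth.d_schedule
    c_sched = truth.c_schedule

    frames: List[UltrasoundFrame] = []
    true_poses: List[RigidTransform] = []
    d_profiles = np.zeros((spec.n_frames, w))

    (x0_lo, x0_hi), (y_lo, y_hi) = (
        (0.0, spec.extent_mm[0]),
        (0.0, spec.extent_mm[1]),
    )
    tilts = (
        rng.uniform(-spec.probe_tilt_deg, spec.probe_tilt_deg, spec.n_frames)
        if spec.probe_tilt_deg > 0
        else np.zeros(spec.n_frames)
    )

    for k in range(spec.n_frames):
        y_t = spec.sweep_y0 + k * spec.frame_step_mm
        if not (y_lo <= y_t <= y_hi):
            raise TrajectoryError(f"frame {k}: sweep position y={y_t:.1f} mm leaves the phantom")
        rot = _R_BASE
        if tilts[k] != 0.0:
            rot = Rotation.from_euler("y", tilts[k], degrees=True).as_matrix() @ _R_BASE
        offs = (rot @ np.column_stack([cols * s_lat, np.zeros(w), np.zeros(w)]).T).T
        face_x = spec.probe_x0 + offs[:, 0]
        face_y = y_t + offs[:, 1]
        if np.any(face_x < x0_lo) or np.any(face_x > x0_hi):
            raise TrajectoryError(f"frame {k}: probe face leaves the phantom laterally")
        f_col = truth.surface_height(face_x, face_y)
        t_z = float(np.mean(f_col)) + d_sched[k] - float(np.mean(offs[:, 2]))
        d_col = np.clip(t_z + offs[:, 2] - f_col, 0.0, None)
        d_profiles[k] = d_col

        # rest-shape depth of each image pixel, per column
        shift = np.stack(
            [_forward_shift(z_rows, d_col[j], c_sched[k], spec.model_mismatch) for j in range(w)],
            axis=1,
        )  # h x w
        omega = z_rows[:, None] - shift
        t_vec = np.array([spec.probe_x0, y_t, t_z])
        depth_dir = rot[:, 1]
        pts = (
            t_vec[None, None, :]
            + offs[None, :, :]
            + omega[:, :, None] * depth_dir[None, None, :]
        )
        coords = np.moveaxis(pts, 2, 0) / truth.spacing
        img = map_coordinates(truth.imaging_volume, coords, order=1, mode="nearest")

        if spec.speckle_strength > 0:
            ray = rng.rayleigh(scale=np.sqrt(2 / np.pi), size=img.shape)
            img = img * (1.0 - spec.speckle_strength + spec.speckle_strength * ray)
        if spec.smooth_sigma > 0:
            img = gaussian_filter(img, spec.smooth_sigma)
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
        img = np.clip(img, 0.0, 1.0)

        pose_true = RigidTransform.from_rotation_translation(
            rot, t_vec, from_frame="U", to_frame="O"
        )
        if spec.pose_noise_rot_deg > 0 or spec.pose_noise_trans_mm > 0:
            rv = rng.normal(0.0, np.deg2rad(spec.pose_noise_rot_deg), 3)
            dt = rng.normal(0.0, spec.pose_noise_trans_mm, 3)
            rot_n = Rotation.from_rotvec(rv).as_matrix() @ rot
            pose_meas = RigidTransform.from_rotation_translation(
                rot_n, t_vec + dt, from_frame="U", to_frame="O"
            )
        else:
            pose_meas = pose_true

        frames.append(
            UltrasoundFrame(
                image=img,
                axial_spacing_mm=s_ax,
                lateral_spacing_mm=s_lat,
                pose=pose_meas,
                frame_id=k,
                timestamp_s=k * 0.1,
            )
        )
        true_poses.append(pose_true)

    return SweepSimulation(
        frames=frames,
        true_poses=true_poses,
        true_d_profiles=d_profiles,
        true_c=c_sched.copy(),
    )
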