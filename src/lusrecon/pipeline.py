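"""Pipeline orchestration: simulate, compensate, compound, overlay, evaluate.

The in-memory functions (:func:`compensate_sweep`, :func:`reconstruct`,
:func:`centerline_error`) chain the library stages and are what the CLI
verbs, the test suite and the evaluation scripts all call; the ``run_*``
functions wrap them with dataset I/O and a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import io as lio
from .compounding import VoxelVolume, compound_sweep, fill_holes
from .errors import InsufficientMatchesError, ValidationError
from .frame import UltrasoundFrame
from .geometry import RigidTransform
from .metrics import Centerline, DistanceReport, distance_stats, extract_centerline
from .overlay import SegmentationVolume, VirtualCamera, overlay_blend, render_segmentation
from .phantom import PhantomSpec, generate_phantom, simulate_sweep
from .pressure import (
    DecayEstimate,
    DisplacementProfile,
    compensate_frame,
    compute_displacement_profile,
    displacement_at_columns,
    estimate_decay_depths,
    extract_contact_line,
    fit_reference_surface,
    match_features,
)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Tunable parameters of the reconstruction pipeline."""

    out_dir: str = "out"
    seed: int = 0
    phantom: Dict = field(default_factory=dict)  # PhantomSpec overrides
    voxel_spacing_mm: float = 0.5
    surface_order: int = 2
    gravity_axis: int = 2
    decay_bounds_mm: Tuple[float, float] = (10.0, 80.0)
    decay_stride: int = 5  # estimate c every this many frame pairs
    hole_fill_radius_mm: float = 1.5
    seg_threshold: float = 0.15  # vessels are hypoechoic: label = intensity < threshold
    prune_mm: float = 3.0
    arc_step_mm: float = 0.5
    overlay_alpha: float = 0.5
    log_level: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if not isinstance(cfg.decay_bounds_mm, tuple):
            cfg.decay_bounds_mm = tuple(cfg.decay_bounds_mm)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decay_bounds_mm"] = list(self.decay_bounds_mm)
        return d


# ---------------------------------------------------------------------
# In-memory pipeline stages
# ---------------------------------------------------------------------


def compensate_sweep(
    frames: Sequence[UltrasoundFrame],
    surface_samples: np.ndarray,
    surface_order: int = 2,
    gravity_axis: int = 2,
    decay_bounds: Tuple[float, float] = (10.0, 80.0),
    decay_stride: int = 5,
) -> Tuple[List[UltrasoundFrame], dict]:
    """Pressure-compensate a tracked sweep.

    Fits the reference surface to the surface samples, derives a
    per-column displacement profile for every frame from its contact
    line, estimates the stress decay depth on every ``decay_stride``-th
    consecutive frame pair (SIFT + RANSAC + the decay objective), holds
    the nearest estimate for in-between frames, and warps each frame.
    Returns the compensated frames and a per-sweep report.
    """
    if len(frames) == 0:
        raise ValidationError("empty sweep")
    surface = fit_reference_surface(surface_samples, surface_order, gravity_axis)
    lines = [extract_contact_line(f) for f in frames]
    profiles = [compute_displacement_profile(line, surface) for line in lines]
    n = len(frames)
    imaging_depth = frames[0].height * frames[0].axial_spacing_mm

    c_est: Dict[int, DecayEstimate] = {}
    for k in range(0, n - 1, max(decay_stride, 1)):
        try:
            matches = match_features(frames[k], frames[k + 1])
        except InsufficientMatchesError:
            continue
        cols0, _, cols1, _ = matches.inlier_arrays()
        d0 = displacement_at_columns(profiles[k], cols0)
        d1 = displacement_at_columns(profiles[k + 1], cols1)
        # transducer-face height difference at the matched columns (gravity axis)
        i0 = np.clip(np.round(cols0).astype(int), 0, frames[k].width - 1)
        i1 = np.clip(np.round(cols1).astype(int), 0, frames[k + 1].width - 1)
        face_offset = (
            lines[k].points[i0, gravity_axis] - lines[k + 1].points[i1, gravity_axis]
        )
        e0, e1 = estimate_decay_depths(
            matches,
            d0,
            d1,
            decay_bounds,
            imaging_depth_mm=imaging_depth,
            face_offset_mm=face_offset,
        )
        # keep the better-converged/lower-objective estimate per frame
        for idx, est in ((k, e0), (k + 1, e1)):
            if idx not in c_est or est.objective < c_est[idx].objective:
                c_est[idx] = est

    report_frames = []
    compensated = []
    est_idx = sorted(c_est)
    for k in range(n):
        if est_idx:
            nearest = min(est_idx, key=lambda i: abs(i - k))
            decay = c_est[nearest]
            held = nearest != k
        else:  # no pair produced matches: fall back to the imaging depth
            decay = DecayEstimate(imaging_depth, (k, k), False, float("inf"), 0)
            held = True
        compensated.append(compensate_frame(frames[k], profiles[k], decay))
        prof = profiles[k]
        report_frames.append(
            {
                "frame_id": int(frames[k].frame_id),
                "c_mm": float(decay.c_mm),
                "converged": bool(decay.converged),
                "held": bool(held),
                "n_matches": int(decay.n_matches),
                "d_mean_mm": float(prof.mean_valid()),
                "d_max_mm": float(prof.d[prof.valid].max()) if prof.valid.any() else 0.0,
                "n_valid_columns": int(prof.valid.sum()),
            }
        )
    report = {
        "n_frames": n,
        "surface_residual_rms_mm": float(surface.residual_rms_mm),
        "decay_bounds_mm": [float(b) for b in decay_bounds],
        "decay_stride": int(decay_stride),
        "frames": report_frames,
    }
    return compensated, report


def reconstruct(
    frames: Sequence[UltrasoundFrame],
    voxel_spacing: float = 0.5,
    fill_radius_mm: Optional[float] = 1.5,
) -> VoxelVolume:
    """Compound a sweep and fill holes."""
    vol = compound_sweep(frames, spacing=voxel_spacing)
    if fill_radius_mm is not None and fill_radius_mm >= voxel_spacing:
        vol = fill_holes(vol, fill_radius_mm)
    return vol


def segment_vessels(
    vol: VoxelVolume, threshold: float = 0.15, min_component_voxels: int = 50
) -> SegmentationVolume:
    """Threshold segmentation of hypoechoic vessels in a compounded volume.

    Connected components smaller than ``min_component_voxels`` (isolated
    dark-speckle blobs) are discarded.
    """
    from scipy import ndimage

    mask = (vol.values < threshold) & vol.filled
    if min_component_voxels > 1 and mask.any():
        comps, n = ndimage.label(mask)
        sizes = np.bincount(comps.ravel())
        small = np.flatnonzero(sizes < min_component_voxels)
        mask &= ~np.isin(comps, small[small > 0])
    return SegmentationVolume(
        labels=mask.astype(np.int32),
        origin=vol.origin,
        spacing=vol.spacing,
        label_names={1: "vessel"},
    )


def centerline_error(
    vol: VoxelVolume,
    truth_centerlines: Sequence[np.ndarray],
    threshold: float = 0.15,
    prune_mm: float = 3.0,
    arc_step_mm: float = 0.5,
) -> Tuple[DistanceReport, Centerline]:
    """Extract vessel centerlines from a reconstruction and compare to truth."""
    seg = segment_vessels(vol, threshold)
    recon = extract_centerline(seg, 1, prune_mm=prune_mm)
    truth = Centerline(branches=[np.asarray(b) for b in truth_centerlines], label="truth")
    report = distance_stats(recon, truth, step_mm=arc_step_mm)
    return report, recon


# ---------------------------------------------------------------------
# Disk-level verbs
# ---------------------------------------------------------------------

VERBS = ("simulate", "compensate", "compound", "overlay", "evaluate")


def _write_manifest(stage_dir: Path, verb: str, config: PipelineConfig, inputs: dict, outputs: list):
    manifest = {
        "verb": verb,
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "inputs": inputs,
        "outputs": outputs,
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_simulate(config: PipelineConfig) -> Path:
    out = Path(config.out_dir) / "simulate"
    try:
        out.mkdir(parents=True, exist_ok=True)
        spec = PhantomSpec(**{"seed": config.seed, **config.phantom})
        truth = generate_phantom(spec)
        sim = simulate_sweep(truth, spec)

        lio.write_frames(out / "frames", sim.frames)
        lio.write_pose_csv(
            out / "poses_true.csv",
            sim.true_poses,
            frame_ids=[f.frame_id for f in sim.frames],
            timestamps=[f.timestamp_s for f in sim.frames],
        )
        np.savetxt(out / "surface_samples.csv", truth.surface_samples, delimiter=",", fmt="%.17g")
        lio.write_volume(out / "truth_volume.mha", truth.volume.astype(np.float32), truth.origin, truth.spacing)
        lio.write_volume(
            out / "truth_vessels.mha", truth.vessel_mask.astype(np.uint8), truth.origin, truth.spacing
        )
        truth_cl = Centerline(branches=list(truth.centerlines), label="truth")
        lio.write_centerline_json(out / "truth_centerlines.json", truth_cl)
        lio.write_centerline_vtk(out / "truth_centerlines.vtk", truth_cl)
        (out / "truth_deformation.json").write_text(
            json.dumps(
                {
                    "d_profiles_mm": sim.true_d_profiles.tolist(),
                    "c_mm": sim.true_c.tolist(),
                }
            )
        )
        (out / "phantom_spec.yaml").write_text(yaml.safe_dump(dataclasses.asdict(spec)))
        _write_manifest(
            out,
            "simulate",
            config,
            inputs={"phantom_spec": dataclasses.asdict(spec)},
            outputs=sorted(p.name for p in out.iterdir()),
        )
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def run_compensate(config: PipelineConfig, data_dir: Optional[Path] = None) -> Path:
    base = Path(config.out_dir)
    data_dir = Path(data_dir) if data_dir else base / "simulate"
    frames_dir = data_dir / "frames"
    samples_path = data_dir / "surface_samples.csv"
    for p in (frames_dir, samples_path):
        if not p.exists():
            raise ValidationError(f"missing input: {p}")
    out = base / "compensate"
    try:
        out.mkdir(parents=True, exist_ok=True)
        frames = lio.read_frames(frames_dir)
        samples = np.loadtxt(samples_path, delimiter=",")
        compensated, report = compensate_sweep(
            frames,
            samples,
            surface_order=config.surface_order,
            gravity_axis=config.gravity_axis,
            decay_bounds=config.decay_bounds_mm,
            decay_stride=config.decay_stride,
        )
        lio.write_frames(out / "frames", compensated)
        (out / "compensation_report.json").write_text(json.dumps(report, indent=1))
        surface = fit_reference_surface(samples, config.surface_order, config.gravity_axis)
        lio.write_surface_yaml(out / "surface.yaml", surface)
        _write_manifest(
            out,
            "compensate",
            config,
            inputs={"frames": str(frames_dir), "surface_samples": str(samples_path)},
            outputs=sorted(p.name for p in out.iterdir()),
        )
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def run_compound(config: PipelineConfig, frames_dir: Optional[Path] = None, name: str = "compound") -> Path:
    base = Path(config.out_dir)
    frames_dir = Path(frames_dir) if frames_dir else base / "compensate" / "frames"
    if not frames_dir.exists():
        raise ValidationError(f"missing input: {frames_dir}")
    out = base / name
    try:
        out.mkdir(parents=True, exist_ok=True)
        frames = lio.read_frames(frames_dir)
        vol = reconstruct(frames, config.voxel_spacing_mm, config.hole_fill_radius_mm)
        lio.write_voxel_volume(out / "volume.mha", vol)
        seg = segment_vessels(vol, config.seg_threshold)
        lio.write_volume(out / "vessels.mha", seg.labels.astype(np.uint8), seg.origin, seg.spacing)
        recon_cl = extract_centerline(seg, 1, prune_mm=config.prune_mm)
        lio.write_centerline_json(out / "centerlines.json", recon_cl)
        lio.write_centerline_vtk(out / "centerlines.vtk", recon_cl)
        _write_manifest(
            out,
            "compound",
            config,
            inputs={"frames": str(frames_dir)},
            outputs=sorted(p.name for p in out.iterdir()),
        )
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def run_overlay(
    config: PipelineConfig,
    seg_path: Optional[Path] = None,
    intrinsics_path: Optional[Path] = None,
    camera_poses_path: Optional[Path] = None,
    base_images_dir: Optional[Path] = None,
) -> Path:
    """Render segmented structures from tracked camera poses and blend.

    Without laparoscope images a neutral gray canvas is used, which still
    exercises the virtual-camera geometry; the augmented frames plus a
    ``transforms.json`` manifest (file, pose) are written in the layout a
    novel-view trainer ingests.
    """
    import imageio.v3 as iio

    base = Path(config.out_dir)
    seg_path = Path(seg_path) if seg_path else base / "compound" / "vessels.mha"
    if not seg_path.exists():
        raise ValidationError(f"missing input: {seg_path}")
    if intrinsics_path is None or camera_poses_path is None:
        raise ValidationError("overlay needs camera intrinsics and pose files")
    out = base / "overlay"
    try:
        out.mkdir(parents=True, exist_ok=True)
        seg = lio.read_segmentation(seg_path, {1: "vessel"})
        intr = lio.read_intrinsics_yaml(intrinsics_path)
        poses, fids, _ = lio.read_pose_csv(camera_poses_path, from_frame="I", to_frame="O")
        transforms = {"intrinsics": str(intrinsics_path), "frames": []}
        for pose, fid in zip(poses, fids):
            cam = VirtualCamera(intrinsics=intr, pose=pose)
            rgba, _ = render_segmentation(cam, seg)
            if base_images_dir is not None:
                img = iio.imread(Path(base_images_dir) / f"frame_{fid:05d}.png").astype(float) / 255.0
                if img.ndim == 2:
                    img = np.stack([img] * 3, axis=-1)
            else:
                img = np.full((intr.height, intr.width, 3), 0.4)
            blended = overlay_blend(img, rgba, config.overlay_alpha)
            name = f"aug_{fid:05d}.png"
            iio.imwrite(out / name, np.round(blended * 255).astype(np.uint8))
            transforms["frames"].append(
                {"file": name, "matrix": [list(map(float, r)) for r in pose.matrix]}
            )
        (out / "transforms.json").write_text(json.dumps(transforms, indent=1))
        _write_manifest(
            out,
            "overlay",
            config,
            inputs={"segmentation": str(seg_path), "poses": str(camera_poses_path)},
            outputs=sorted(p.name for p in out.iterdir()),
        )
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def run_evaluate(
    config: PipelineConfig,
    recon_path: Optional[Path] = None,
    truth_path: Optional[Path] = None,
) -> Path:
    base = Path(config.out_dir)
    recon_path = Path(recon_path) if recon_path else base / "compound" / "centerlines.json"
    truth_path = Path(truth_path) if truth_path else base / "simulate" / "truth_centerlines.json"
    for p in (recon_path, truth_path):
        if not p.exists():
            raise ValidationError(f"missing input: {p}")
    out = base / "evaluate"
    try:
        out.mkdir(parents=True, exist_ok=True)
        recon = lio.read_centerline_json(recon_path)
        truth = lio.read_centerline_json(truth_path)
        report = distance_stats(recon, truth, step_mm=config.arc_step_mm)
        (out / "centerline_distance.json").write_text(json.dumps(report.to_dict(), indent=1))
        with (out / "centerline_distance.csv").open("w") as fh:
            d = report.to_dict()
            fh.write(",".join(d.keys()) + "\n")
            fh.write(",".join(repr(v) for v in d.values()) + "\n")
        _write_manifest(
            out,
            "evaluate",
            config,
            inputs={"recon": str(recon_path), "truth": str(truth_path)},
            outputs=sorted(p.name for p in out.iterdir()),
        )
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def run_pipeline(config: PipelineConfig, verb: str, **kwargs) -> Path:
    """Dispatch one pipeline verb; artifacts land under ``config.out_dir``."""
    if verb == "simulate":
        return run_simulate(config)
    if verb == "compensate":
        return run_compensate(config, **kwargs)
    if verb == "compound":
        return run_compound(config, **kwargs)
    if verb == "overlay":
        return run_overlay(config, **kwargs)
    if verb == "evaluate":
        return run_evaluate(config, **kwargs)
    raise ValidationError(f"unknown verb {verb!r}; expected one of {VERBS}")
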