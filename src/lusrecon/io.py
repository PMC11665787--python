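"""Readers and writers for the on-disk dataset formats.

Formats are deliberately plain: 16-bit PNG frames with a JSON manifest,
pose tables as CSV (frame_id, timestamp_s, 16 row-major matrix entries)
or JSON, intrinsics/pattern/surface as YAML, volumes as MetaImage (.mha)
or NIfTI (.nii/.nii.gz) with origin and spacing metadata, centerlines as
JSON polylines or VTK legacy ASCII polydata.  Every writer round-trips
through its reader with poses preserved to better than 1e-12 and spacing
exact.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk
import yaml

from .compounding import VoxelVolume
from .errors import ValidationError
from .frame import UltrasoundFrame
from .geometry import CameraIntrinsics, PatternGeometry, RigidTransform
from .metrics import Centerline
from .overlay import SegmentationVolume
from .pressure import ReferenceSurface

_FLOAT_FMT = "{:.17g}"


# ---------------------------------------------------------------------
# Poses
# ---------------------------------------------------------------------


def write_pose_csv(
    path: Union[str, Path],
    poses: Sequence[RigidTransform],
    frame_ids: Optional[Sequence[int]] = None,
    timestamps: Optional[Sequence[float]] = None,
) -> None:
    path = Path(path)
    n = len(poses)
    frame_ids = list(frame_ids) if frame_ids is not None else list(range(n))
    timestamps = list(timestamps) if timestamps is not None else [0.0] * n
    header = ["frame_id", "timestamp_s"] + [f"m{r}{c}" for r in range(4) for c in range(4)]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for fid, ts, pose in zip(frame_ids, timestamps, poses):
            row = [fid, _FLOAT_FMT.format(ts)]
            row += [_FLOAT_FMT.format(v) for v in pose.matrix.ravel()]
            writer.writerow(row)


def read_pose_csv(
    path: Union[str, Path], from_frame: str = "U", to_frame: str = "O"
) -> Tuple[List[RigidTransform], List[int], List[float]]:
    path = Path(path)
    poses, fids, tss = [], [], []
    with path.open(newline="") as fh:
        for rec in csv.DictReader(fh):
            m = np.array(
                [float(rec[f"m{r}{c}"]) for r in range(4) for c in range(4)]
            ).reshape(4, 4)
            poses.append(RigidTransform(m, from_frame=from_frame, to_frame=to_frame))
            fids.append(int(rec["frame_id"]))
            tss.append(float(rec["timestamp_s"]))
    return poses, fids, tss


def write_pose_json(path, poses, frame_ids=None, timestamps=None) -> None:
    n = len(poses)
    frame_ids = list(frame_ids) if frame_ids is not None else list(range(n))
    timestamps = list(timestamps) if timestamps is not None else [0.0] * n
    records = [
        {
            "frame_id": int(fid),
            "timestamp_s": float(ts),
            "matrix": [list(map(float, row)) for row in pose.matrix],
        }
        for fid, ts, pose in zip(frame_ids, timestamps, poses)
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_pose_json(path, from_frame: str = "U", to_frame: str = "O"):
    records = json.loads(Path(path).read_text())
    poses = [
        RigidTransform(np.array(r["matrix"], dtype=float), from_frame, to_frame)
        for r in records
    ]
    return (
        poses,
        [r["frame_id"] for r in records],
        [r["timestamp_s"] for r in records],
    )


# ---------------------------------------------------------------------
# YAML configuration objects
# ---------------------------------------------------------------------


def write_intrinsics_yaml(path, intr: CameraIntrinsics) -> None:
    data = {
        "fx": float(intr.fx),
        "fy": float(intr.fy),
        "cx": float(intr.cx),
        "cy": float(intr.cy),
        "width": int(intr.width),
        "height": int(intr.height),
        "distortion": [float(k) for k in intr.distortion],
    }
    Path(path).write_text(yaml.safe_dump(data))


def read_intrinsics_yaml(path) -> CameraIntrinsics:
    data = yaml.safe_load(Path(path).read_text())
    return CameraIntrinsics(
        fx=data["fx"],
        fy=data["fy"],
        cx=data["cx"],
        cy=data["cy"],
        width=data["width"],
        height=data["height"],
        distortion=tuple(data.get("distortion", ())),
    )


def write_pattern_yaml(path, pattern: PatternGeometry) -> None:
    Path(path).write_text(
        yaml.safe_dump({"points_mm": [list(map(float, p)) for p in pattern.points]})
    )


def read_pattern_yaml(path) -> PatternGeometry:
    data = yaml.safe_load(Path(path).read_text())
    return PatternGeometry(points=np.array(data["points_mm"], dtype=float))


def write_surface_yaml(path, surface: ReferenceSurface) -> None:
    data = {
        "order": int(surface.order),
        "coefficients": [float(c) for c in surface.coefficients],
        "domain": [[float(v) for v in ax] for ax in surface.domain],
        "residual_rms_mm": float(surface.residual_rms_mm),
        "height_axis": int(surface.height_axis),
    }
    Path(path).write_text(yaml.safe_dump(data))


def read_surface_yaml(path) -> ReferenceSurface:
    data = yaml.safe_load(Path(path).read_text())
    return ReferenceSurface(
        order=data["order"],
        coefficients=np.array(data["coefficients"], dtype=float),
        domain=(tuple(data["domain"][0]), tuple(data["domain"][1])),
        residual_rms_mm=data["residual_rms_mm"],
        height_axis=data["height_axis"],
    )


# ---------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------


def write_volume(
    path,
    values: np.ndarray,
    origin: Sequence[float],
    spacing: Union[float, Sequence[float]],
) -> None:
    """Write a scalar grid (x, y, z index order) as MHA or NIfTI."""
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(values, (2, 1, 0))))
    img.SetOrigin(tuple(float(v) for v in origin))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a volume; returns (values in (x, y, z) order, origin, spacing)."""
    img = sitk.ReadImage(str(path))
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return values, np.array(img.GetOrigin()), np.array(img.GetSpacing())


def write_voxel_volume(path, vol: VoxelVolume) -> None:
    """Write a compounded volume plus a companion fill-state label volume.

    The companion ``<stem>_mask`` labels voxels 0 = empty, 1 = directly
    compounded, 2 = hole-filled.
    """
    path = Path(path)
    write_volume(path, vol.values.astype(np.float32), vol.origin, vol.spacing)
    state = np.zeros(vol.shape, dtype=np.uint8)
    state[vol.counts > 0] = 1
    state[vol.hole_filled] = 2
    suffixes = "".join(path.suffixes)
    stem = path.name[: -len(suffixes)] if suffixes else path.name
    write_volume(path.with_name(stem + "_mask" + suffixes), state, vol.origin, vol.spacing)


def read_segmentation(path, label_names: Optional[Dict[int, str]] = None) -> SegmentationVolume:
    values, origin, spacing = read_volume(path)
    if abs(spacing[0] - spacing[1]) > 1e-9 or abs(spacing[0] - spacing[2]) > 1e-9:
        raise ValidationError("segmentation volumes must have isotropic spacing")
    return SegmentationVolume(
        labels=values.astype(np.int32),
        origin=origin,
        spacing=float(spacing[0]),
        label_names=label_names or {},
    )


# ---------------------------------------------------------------------
# Ultrasound frames (PNG stack + JSON manifest)
# ---------------------------------------------------------------------


def write_frames(
    directory,
    frames: Sequence[UltrasoundFrame],
    pose_filename: str = "poses.csv",
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, fr in enumerate(frames):
        name = f"frame_{k:05d}.png"
        iio.imwrite(
            directory / name,
            np.round(np.clip(fr.image, 0, 1) * 65535).astype(np.uint16),
        )
        rec = {
            "file": name,
            "frame_id": int(fr.frame_id),
            "timestamp_s": float(fr.timestamp_s),
            "axial_spacing_mm": float(fr.axial_spacing_mm),
            "lateral_spacing_mm": float(fr.lateral_spacing_mm),
            "row0_offset_mm": float(fr.row0_offset_mm),
        }
        if fr.valid_mask is not None:
            mask_name = f"frame_{k:05d}_mask.png"
            iio.imwrite(directory / mask_name, fr.valid_mask.astype(np.uint8) * 255)
            rec["mask_file"] = mask_name
        manifest.append(rec)
    (directory / "frames.json").write_text(json.dumps(manifest, indent=1))
    poses = [fr.pose for fr in frames]
    if all(p is not None for p in poses):
        write_pose_csv(
            directory / pose_filename,
            poses,
            frame_ids=[fr.frame_id for fr in frames],
            timestamps=[fr.timestamp_s for fr in frames],
        )


def read_frames(directory, pose_filename: str = "poses.csv") -> List[UltrasoundFrame]:
    directory = Path(directory)
    manifest = json.loads((directory / "frames.json").read_text())
    poses = {}
    pose_path = directory / pose_filename
    if pose_path.exists():
        plist, fids, _ = read_pose_csv(pose_path)
        poses = dict(zip(fids, plist))
    frames = []
    for rec in manifest:
        img = iio.imread(directory / rec["file"]).astype(float) / 65535.0
        mask = None
        if "mask_file" in rec:
            mask = iio.imread(directory / rec["mask_file"]) > 127
        frames.append(
            UltrasoundFrame(
                image=img,
                axial_spacing_mm=rec["axial_spacing_mm"],
                lateral_spacing_mm=rec["lateral_spacing_mm"],
                pose=poses.get(rec["frame_id"]),
                frame_id=rec["frame_id"],
                timestamp_s=rec["timestamp_s"],
                row0_offset_mm=rec["row0_offset_mm"],
                valid_mask=mask,
            )
        )
    return frames


# ---------------------------------------------------------------------
# Centerlines
# ---------------------------------------------------------------------


def write_centerline_json(path, centerline: Centerline) -> None:
    data = {
        "label": centerline.label,
        "degenerate": bool(centerline.degenerate),
        "branches_mm": [[list(map(float, p)) for p in b] for b in centerline.branches],
    }
    Path(path).write_text(json.dumps(data))


def read_centerline_json(path) -> Centerline:
    data = json.loads(Path(path).read_text())
    return Centerline(
        branches=[np.array(b, dtype=float) for b in data["branches_mm"]],
        label=data.get("label", ""),
        degenerate=data.get("degenerate", False),
    )


def write_centerline_vtk(path, centerline: Centerline) -> None:
    """VTK legacy ASCII polydata with one polyline cell per branch."""
    pts = centerline.points()
    lines = []
    offset = 0
    for b in centerline.branches:
        lines.append([len(b)] + list(range(offset, offset + len(b))))
        offset += len(b)
    with Path(path).open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvessel centerlines\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        total = sum(len(l) for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(v) for v in l) + "\n")
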