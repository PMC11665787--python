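"""The tracked 2D ultrasound frame container.

A frame couples a cropped B-mode image with its physical pixel spacing and
its rigid pose in the optical-tracker frame ``O``.  Image axes follow the
B-mode convention used throughout the toolkit: row index = axial depth
(row 0 at the transducer face), column index = lateral position.
Pressure compensation may extend the canvas above the original transducer
face; ``row0_offset_mm`` records the axial coordinate of row 0 after such
padding (zero for raw frames, negative after compensation padding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ValidationError
from .geometry import RigidTransform


@dataclass
class UltrasoundFrame:
    image: np.ndarray  # H x W, intensities in [0, 1]
    axial_spacing_mm: float  # mm per pixel along rows (depth)
    lateral_spacing_mm: float  # mm per pixel along columns
    pose: Optional[RigidTransform] = None  # frame U -> O
    frame_id: int = 0
    timestamp_s: float = 0.0
    row0_offset_mm: float = 0.0
    valid_mask: Optional[np.ndarray] = None  # False where pixels carry no content

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValidationError("ultrasound image must be 2-D grayscale")
        if not np.all(np.isfinite(img)):
            raise ValidationError("ultrasound image contains non-finite intensities")
        if img.size and (img.min() < -1e-9 or img.max() > 1 + 1e-9):
            raise ValidationError("intensities must lie in [0, 1]")
        self.image = img
        if self.axial_spacing_mm <= 0 or self.lateral_spacing_mm <= 0:
            raise ValidationError("pixel spacing must be positive")
        if self.valid_mask is not None:
            mask = np.asarray(self.valid_mask, dtype=bool)
            if mask.shape != img.shape:
                raise ValidationError("valid_mask must match the image shape")
            self.valid_mask = mask

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def with_pose(self, pose: RigidTransform) -> "UltrasoundFrame":
        return replace(self, pose=pose)

    def depth_of_row(self, row) -> np.ndarray:
        """Axial coordinate (mm, frame U) of pixel centers at ``row``."""
        return np.asarray(row, dtype=float) * self.axial_spacing_mm + self.row0_offset_mm
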