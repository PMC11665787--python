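"""Exception hierarchy for the reconstruction toolkit."""


class LusreconError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(LusreconError, ValueError):
    """Input fails a precondition (shape, finiteness, sign, missing field)."""


class ChainIncompatibilityError(LusreconError):
    """Adjacent transforms in a chain do not share a coordinate frame."""

    def __init__(self, left_label: str, right_label: str, position: int):
        self.left_label = left_label
        self.right_label = right_label
        self.position = position
        super().__init__(
            f"transform chain broken at position {position}: expected frame "
            f"{left_label!r} but next transform maps from {right_label!r}"
        )


class DegenerateGeometryError(LusreconError):
    """Geometry too degenerate for the requested fit (collinear points, rank-deficient design)."""


class InsufficientCorrespondencesError(LusreconError):
    """Fewer point correspondences than the pose solver needs."""


class InsufficientMatchesError(LusreconError):
    """Feature matching produced too few inlier matches; caller should fall back."""


class DomainError(LusreconError):
    """Query lies entirely outside the fitted surface domain."""


class GenerationError(LusreconError):
    """Synthetic phantom specification is geometrically infeasible."""


class TrajectoryError(LusreconError):
    """Simulated probe trajectory leaves the phantom surface domain."""
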