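"""Physical calibration, embryo coordinate conventions, and ellipsoid volumes.

The canonical embryo frame used throughout the package: coordinates in µm,
origin at the embryo centre, x along the long axis, y along the short axis.
Videos are oriented so that the pole containing the meiotic spindle sits at
negative x (the "left") on the first frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidDimensionError, InvalidMeasurementError

#: Minimum embryo long-axis length (µm) for a video to be usable for
#: ER-ring tracking; shorter embryos are tilted relative to the focal plane.
MIN_EMBRYO_LENGTH_UM = 35.0


@dataclass(frozen=True)
class EllipsoidDims:
    """Semi-axes of an ellipsoid, in µm."""

    a_um: float
    b_um: float
    c_um: float

    def __post_init__(self) -> None:
        if not (self.a_um > 0 and self.b_um > 0 and self.c_um > 0):
            raise InvalidDimensionError(
                f"semi-axes must be positive, got {(self.a_um, self.b_um, self.c_um)}"
            )

    @classmethod
    def from_axes(cls, long_axis_um: float, short_axis_um: float) -> "EllipsoidDims":
        """Build a prolate spheroid from full axis lengths (long, short, short)."""
        return cls(long_axis_um / 2.0, short_axis_um / 2.0, short_axis_um / 2.0)

    @classmethod
    def sphere(cls, diameter_um: float) -> "EllipsoidDims":
        r = diameter_um / 2.0
        return cls(r, r, r)


@dataclass(frozen=True)
class EmbryoFrame:
    """Pose of an ellipsoid embryo within image coordinates.

    ``orientation_deg`` is the rotation (counter-clockwise) of the embryo long
    axis relative to the image x axis; ``origin`` is the embryo centre in µm.
    """

    long_axis_um: float
    short_axis_um: float
    origin: tuple[float, float] = (0.0, 0.0)
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.long_axis_um >= self.short_axis_um > 0):
            raise InvalidDimensionError(
                "require long_axis_um >= short_axis_um > 0, got "
                f"{(self.long_axis_um, self.short_axis_um)}"
            )


def ellipsoid_volume(dims: EllipsoidDims) -> float:
    """Volume of an ellipsoid, (4/3)·π·a·b·c, in µm³."""
    return (4.0 / 3.0) * math.pi * dims.a_um * dims.b_um * dims.c_um


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (2.5 → 3)."""
    return int(math.floor(x + 0.5))


def volume_ratio(
    numerator: EllipsoidDims, denominator: EllipsoidDims
) -> tuple[float, int]:
    """Ratio of two ellipsoid volumes.

    Returns ``(raw, nearest_int)`` where the integer uses half-up rounding,
    matching how such fold-differences are conventionally reported.
    """
    v_num = ellipsoid_volume(numerator)
    v_den = ellipsoid_volume(denominator)
    if v_den <= 0:  # unreachable given EllipsoidDims invariants; defensive
        raise InvalidDimensionError("denominator ellipsoid has zero volume")
    raw = v_num / v_den
    return raw, round_half_up(raw)


def qc_embryo_length(measured_length_um: float) -> bool:
    """Inclusion filter for tracking: pass iff the embryo is longer than 35 µm.

    The boundary is strict: exactly 35 µm fails.
    """
    if measured_length_um < 0:
        raise InvalidMeasurementError(
            f"embryo length cannot be negative: {measured_length_um}"
        )
    return measured_length_um > MIN_EMBRYO_LENGTH_UM


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


def normalize_orientation(
    track_points: Sequence[Sequence[float]] | np.ndarray,
    spindle_start: Sequence[float],
    embryo: EmbryoFrame,
) -> np.ndarray:
    """Map points into the canonical embryo frame (spindle pole at left).

    Applies the rigid transform (translation to the embryo centre, rotation by
    minus the embryo orientation, and a 180° flip if needed so that the
    spindle's first position has x ≤ 0). Pairwise distances are preserved.
    """
    pts = np.atleast_2d(np.asarray(track_points, dtype=float))
    if pts.shape[1] != 2:
        raise InvalidDimensionError("track points must be 2-D (x, y)")
    origin = np.asarray(embryo.origin, dtype=float)
    rot = _rotation_matrix(-embryo.orientation_deg)
    out = (pts - origin) @ rot.T
    spindle = (np.asarray(spindle_start, dtype=float) - origin) @ rot.T
    if spindle[0] > 0:
        out = -out  # 180° rotation about the centre
    return out
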