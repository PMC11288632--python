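"""Phase-segmented trajectory metrics for the sperm ER ring.

The sperm contents are tracked as the centre of the maternal-ER ring around
the sperm DNA in 5-s-interval time-lapse video, and each meiotic phase
(metaphase/anaphase I and II, delimited by ER-morphology transitions supplied
as annotations) is quantified separately:

* maximum x- and y-axis displacement — per-axis (max − min) coordinate;
* displacement — Euclidean distance from the first to the last point;
* distance traveled — summed point-to-point path length;
* maximum average velocity — the maximum of 3-point moving averages of the
  frame-to-frame speeds;
* duration — (last frame − first frame) × frame interval.

All metrics are in µm / µm s⁻¹, computed in the canonical embryo frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import NoDataError

DEFAULT_FRAME_INTERVAL_S = 5.0


@dataclass
class Trajectory:
    """Time-stamped 2-D point series for one tracked object."""

    frames: np.ndarray  # int frame indices, strictly increasing
    x_um: np.ndarray
    y_um: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    embryo_id: str = ""
    object_type: str = "sperm_ring"  # "sperm_ring" | "spindle"
    track_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.frames.size < 1:
            raise NoDataError("trajectory must contain at least one point")
        if not (len(self.frames) == len(self.x_um) == len(self.y_um)):
            raise ValueError("frames/x/y length mismatch")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    @classmethod
    def from_points(
        cls, points: np.ndarray, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S, **kw
    ) -> "Trajectory":
        pts = np.asarray(points, dtype=float)
        return cls(np.arange(len(pts)), pts[:, 0], pts[:, 1],
                   frame_interval_s=frame_interval_s, **kw)


@dataclass(frozen=True)
class PhaseWindow:
    """Inclusive frame window of one meiotic phase."""

    phase: str
    first_frame: int
    last_frame: int

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError(
                f"window {self.phase}: first_frame {self.first_frame} > "
                f"last_frame {self.last_frame}"
            )


@dataclass
class SubTrack:
    """A phase-restricted portion of a trajectory."""

    phase: str
    trajectory: Optional[Trajectory]
    complete: bool


@dataclass
class TrackMetrics:
    phase: str
    max_x_disp_um: float
    max_y_disp_um: float
    net_displacement_um: float
    path_length_um: float
    max_avg_velocity_um_s: Optional[float]  # None when the phase is too short
    duration_s: float
    complete: bool = True


def split_by_phase(track: Trajectory, windows: Sequence[PhaseWindow]) -> list[SubTrack]:
    """Restrict a trajectory to each phase window.

    A sub-track holds exactly the points whose frame indices fall inside the
    (inclusive) window. A phase is flagged complete only when the filmed
    track spans the whole window; incompletely filmed phases are excluded
    from quantification by the caller. An empty sub-track is flagged
    incomplete, not an error.
    """
    out: list[SubTrack] = []
    span = (int(track.frames[0]), int(track.frames[-1]))
    for w in windows:
        sel = (track.frames >= w.first_frame) & (track.frames <= w.last_frame)
        if not sel.any():
            out.append(SubTrack(w.phase, None, False))
            continue
        sub = Trajectory(
            track.frames[sel], track.x_um[sel], track.y_um[sel],
            frame_interval_s=track.frame_interval_s,
            embryo_id=track.embryo_id, object_type=track.object_type,
            track_id=track.track_id,
        )
        complete = span[0] <= w.first_frame and span[1] >= w.last_frame
        out.append(SubTrack(w.phase, sub, complete))
    return out


def max_axis_displacement(sub: Trajectory) -> tuple[float, float]:
    """Per-axis (max − min) coordinate over the phase track."""
    if len(sub) < 1:
        raise NoDataError("empty track")
    return (
        float(sub.x_um.max() - sub.x_um.min()),
        float(sub.y_um.max() - sub.y_um.min()),
    )


def net_displacement(sub: Trajectory) -> float:
    """Euclidean distance between the first and last point of the phase."""
    if len(sub) < 1:
        raise NoDataError("empty track")
    return float(np.hypot(sub.x_um[-1] - sub.x_um[0], sub.y_um[-1] - sub.y_um[0]))


def path_length(sub: Trajectory) -> float:
    """Total length traveled: sum of consecutive point-to-point distances."""
    if len(sub) < 1:
        raise NoDataError("empty track")
    return float(np.hypot(np.diff(sub.x_um), np.diff(sub.y_um)).sum())


def step_speeds(sub: Trajectory) -> np.ndarray:
    """Frame-to-frame scalar speeds (µm/s); gaps divide by the actual time."""
    d = np.hypot(np.diff(sub.x_um), np.diff(sub.y_um))
    dt = np.diff(sub.frames) * sub.frame_interval_s
    return d / dt


def max_avg_velocity(sub: Trajectory, window: int = 3) -> Optional[float]:
    """Maximum of trailing ``window``-point moving averages of speeds.

    With k frame-to-frame speeds there are k − window + 1 moving-average
    windows; returns None (metric omitted) when fewer than ``window`` speeds
    are available.
    """
    v = step_speeds(sub)
    if v.size < window:
        return None
    kernel = np.ones(window) / window
    mov = np.convolve(v, kernel, mode="valid")
    return float(mov.max())


def phase_duration(window: PhaseWindow, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> float:
    """(last frame − first frame) × frame interval, in seconds."""
    return (window.last_frame - window.first_frame) * frame_interval_s


def phase_metrics(
    track: Trajectory,
    windows: Sequence[PhaseWindow],
    velocity_window: int = 3,
    include_incomplete: bool = False,
) -> list[TrackMetrics]:
    """All per-phase metrics for one trajectory.

    Incompletely filmed phases are skipped unless ``include_incomplete``.
    """
    results = []
    win_by_phase = {w.phase: w for w in windows}
    for sub in split_by_phase(track, windows):
        if sub.trajectory is None:
            continue
        if not sub.complete and not include_incomplete:
            continue
        t = sub.trajectory
        mx, my = max_axis_displacement(t)
        results.append(TrackMetrics(
            phase=sub.phase,
            max_x_disp_um=mx,
            max_y_disp_um=my,
            net_displacement_um=net_displacement(t),
            path_length_um=path_length(t),
            max_avg_velocity_um_s=max_avg_velocity(t, velocity_window),
            duration_s=phase_duration(win_by_phase[sub.phase], track.frame_interval_s),
            complete=sub.complete,
        ))
    return results
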