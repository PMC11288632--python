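"""Sperm/spindle capture-event classification from paired trajectories.

A capture event is called when the sperm contents (tracked as the ER ring
centre) come within a threshold centre-to-centre distance of the meiotic
spindle — 5.5 µm by default — and then stop moving relative to the spindle.
"Stopped moving" is operationalised as some run of ``stuck_window_frames``
consecutive frames whose cumulative relative displacement stays below
``stuck_disp_um``; both parameters are reported with every result because no
numeric stuck criterion is standard. Distances are evaluated on 2-D
projected centres (live capture calls are made from single-focal-plane
time-lapse).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError
from .tracks import Trajectory

#: Frame-gap length above which a below-threshold episode is split in two.
MAX_EPISODE_GAP_FRAMES = 3


@dataclass(frozen=True)
class CaptureConfig:
    threshold_um: float = 5.5
    stuck_window_frames: int = 6
    stuck_disp_um: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_um <= 0:
            raise ValueError("threshold_um must be positive")
        if self.stuck_window_frames < 2:
            raise ValueError("stuck_window_frames must be >= 2")


@dataclass
class CaptureEvent:
    embryo_id: str
    min_distance_um: float
    approach_frame: Optional[int]  # first frame below threshold
    classification: str  # none | stable | transient | transient_then_stable
    n_threshold_crossings: int
    insufficient_data: bool = False
    config: CaptureConfig = CaptureConfig()

    @property
    def captured(self) -> bool:
        return self.classification in ("stable", "transient_then_stable")


def center_distance_series(
    sperm: Trajectory, spindle: Trajectory
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame Euclidean distance on the frames both tracks share.

    Returns ``(frames, distances_um, relative_positions)`` where relative
    positions are sperm − spindle on the shared frames.
    """
    shared, ia, ib = np.intersect1d(sperm.frames, spindle.frames, return_indices=True)
    if shared.size == 0:
        raise AlignmentError("tracks share no frames")
    rel = np.column_stack([
        sperm.x_um[ia] - spindle.x_um[ib],
        sperm.y_um[ia] - spindle.y_um[ib],
    ])
    dist = np.hypot(rel[:, 0], rel[:, 1])
    return shared, dist, rel


def _episodes(below: np.ndarray, frames: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i0, i1] of maximal below-threshold runs, split at frame
    gaps longer than MAX_EPISODE_GAP_FRAMES."""
    eps: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(below):
        gap = (
            i > 0 and flag and below[i - 1]
            and frames[i] - frames[i - 1] > MAX_EPISODE_GAP_FRAMES
        )
        if flag and (start is None):
            start = i
        elif flag and gap:
            eps.append((start, i - 1))
            start = i
        elif not flag and start is not None:
            eps.append((start, i - 1))
            start = None
    if start is not None:
        eps.append((start, len(below) - 1))
    return eps


def _has_stuck_run(rel: np.ndarray, i0: int, i1: int, config: CaptureConfig) -> bool:
    """Does [i0, i1] contain stuck_window_frames consecutive frames whose total
    relative path length is below stuck_disp_um?"""
    w = config.stuck_window_frames
    if i1 - i0 + 1 < w:
        return False
    steps = np.hypot(*(np.diff(rel[i0:i1 + 1], axis=0).T))
    # w frames → w-1 steps per window
    for s in range(0, steps.size - (w - 1) + 1):
        if steps[s:s + w - 1].sum() < config.stuck_disp_um:
            return True
    return False


def classify_capture(
    distance_series: np.ndarray,
    relative_positions: np.ndarray,
    config: CaptureConfig = CaptureConfig(),
    frames: Optional[np.ndarray] = None,
    embryo_id: str = "",
) -> CaptureEvent:
    """Classify the approach of the sperm contents to the spindle.

    Below-threshold episodes are identified; the final episode is *stable*
    when it persists to the end of the series and contains a stuck run.
    Earlier episodes that end with the distance rising back above threshold
    are *transient*. The overall classification summarises the episode
    sequence; ``n_threshold_crossings`` counts threshold crossings (either
    direction) before the final episode begins.
    """
    d = np.asarray(distance_series, dtype=float)
    rel = np.asarray(relative_positions, dtype=float)
    frames = np.arange(d.size) if frames is None else np.asarray(frames)
    if d.size < config.stuck_window_frames:
        return CaptureEvent(embryo_id, float(d.min()) if d.size else np.nan,
                            None, "none", 0, insufficient_data=True, config=config)

    below = d < config.threshold_um
    min_d = float(d.min())
    eps = _episodes(below, frames)
    if not eps:
        return CaptureEvent(embryo_id, min_d, None, "none", 0, config=config)

    approach_frame = int(frames[eps[0][0]])
    final = eps[-1]
    final_persists = final[1] == d.size - 1
    final_stable = final_persists and _has_stuck_run(rel, final[0], final[1], config)

    crossings_before = int(
        np.count_nonzero(np.diff(below[: final[0]].astype(int)) != 0)
    )
    n_transient = len(eps) - (1 if final_stable else 0)

    if final_stable and n_transient == 0:
        cls = "stable"
    elif final_stable:
        cls = "transient_then_stable"
    else:
        cls = "transient"
    return CaptureEvent(embryo_id, min_d, approach_frame, cls,
                        crossings_before, config=config)


def classify_tracks(
    sperm: Trajectory,
    spindle: Trajectory,
    config: CaptureConfig = CaptureConfig(),
    embryo_id: str = "",
) -> CaptureEvent:
    """Convenience: align two tracks and classify in one call."""
    frames, dist, rel = center_distance_series(sperm, spindle)
    return classify_capture(dist, rel, config, frames=frames,
                            embryo_id=embryo_id or sperm.embryo_id)


def capture_contingency(
    events_by_group: dict[str, Sequence[CaptureEvent]]
) -> list[list[int]]:
    """2×k contingency counts [[captured, not captured], ...] per group.

    Captured = classification in {stable, transient_then_stable}. Empty
    groups yield a zero row (kept, with a warning).
    """
    import warnings

    table = []
    for name, events in events_by_group.items():
        if not events:
            warnings.warn(f"group {name!r} has no events; zero row retained")
            table.append([0, 0])
            continue
        cap = sum(1 for e in events if e.captured)
        table.append([cap, len(events) - cap])
    return table
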