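"""File formats, configuration, and end-to-end orchestration.

Stacks are multi-page TIFF (channel-major) with a YAML calibration sidecar;
tracks, phases, ROI tables and results are CSV; configuration is YAML. All
positions in output files are in µm; frame and pixel indices are 0-based.
Every output CSV embeds the resolved config hash and seed as a comment line
for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError
from .tracks import Trajectory, PhaseWindow

log = logging.getLogger("zygoquant")


@dataclass
class ImageStack:
    """Multi-channel 3-D intensity array with physical calibration."""

    voxels: np.ndarray  # (channel, z, y, x)
    channel_names: tuple[str, ...]
    pixel_size_um: float
    z_step_um: float
    frame_interval_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be (channel, z, y, x)")
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match channel axis")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration values must be positive")
        if float(self.voxels.min()) < 0:
            raise ValueError("intensities must be non-negative")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.voxels[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channel_names}")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    meta = {
        "channel_names": list(stack.channel_names),
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "frame_interval_s": stack.frame_interval_s,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))
    return path


def read_stack(
    path: str | Path,
    calibration: Optional[dict] = None,
) -> ImageStack:
    """Read a TIFF stack; calibration comes from the sidecar, else ``calibration``.

    ``calibration`` must supply pixel_size_um and z_step_um (and optionally
    channel_names, frame_interval_s) when no sidecar is present.
    """
    path = Path(path)
    try:
        voxels = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    meta: dict = {}
    if _sidecar(path).exists():
        meta = yaml.safe_load(_sidecar(path).read_text()) or {}
    if calibration:
        for k, v in calibration.items():
            meta.setdefault(k, v)
    if "pixel_size_um" not in meta or "z_step_um" not in meta:
        raise FormatError(
            f"stack {path} has no calibration sidecar; supply pixel_size_um "
            "and z_step_um via the config"
        )
    voxels = np.asarray(voxels)
    if voxels.ndim == 3:
        voxels = voxels[None]
    names = tuple(meta.get("channel_names") or
                  [f"ch{i}" for i in range(voxels.shape[0])])
    return ImageStack(voxels, names, meta["pixel_size_um"], meta["z_step_um"],
                      meta.get("frame_interval_s"))


def write_tracks(tracks: Sequence[Trajectory], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for t in tracks:
        for f, x, y in zip(t.frames, t.x_um, t.y_um):
            rows.append({
                "track_id": t.track_id or t.embryo_id,
                "embryo_id": t.embryo_id,
                "object": t.object_type,
                "frame": int(f),
                "x_um": float(x),
                "y_um": float(y),
            })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_tracks(
    path: str | Path,
    pixel_size_um: Optional[float] = None,
    frame_interval_s: float = 5.0,
) -> list[Trajectory]:
    """Read a track CSV into trajectories, converting pixels to µm if needed.

    Columns: ``track_id, frame`` plus either ``x_um, y_um`` or ``x_px, y_px``
    (the latter requires ``pixel_size_um``). Optional ``embryo_id, object``.
    Rows are sorted by frame; duplicate (track, frame) pairs are an error.
    """
    df = pd.read_csv(path, comment="#")
    required = {"track_id", "frame"}
    if not required.issubset(df.columns):
        raise FormatError(f"track CSV must have columns {sorted(required)}")
    if {"x_um", "y_um"}.issubset(df.columns):
        df["_x"], df["_y"] = df["x_um"], df["y_um"]
    elif {"x_px", "y_px"}.issubset(df.columns):
        if pixel_size_um is None:
            raise FormatError("pixel-unit tracks require pixel_size_um")
        df["_x"] = df["x_px"] * pixel_size_um
        df["_y"] = df["y_px"] * pixel_size_um
    else:
        raise FormatError("track CSV needs x_um/y_um or x_px/y_px columns")
    if df.duplicated(["track_id", "frame"]).any():
        raise FormatError("duplicate (track_id, frame) rows")
    out = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        out.append(Trajectory(
            g["frame"].to_numpy(), g["_x"].to_numpy(), g["_y"].to_numpy(),
            frame_interval_s=frame_interval_s,
            embryo_id=str(g["embryo_id"].iloc[0]) if "embryo_id" in g else str(tid),
            object_type=str(g["object"].iloc[0]) if "object" in g else "sperm_ring",
            track_id=str(tid),
        ))
    return out


def read_mtrackj_points(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float = 5.0,
) -> list[Trajectory]:
    """Import an MTrackJ-style exported point list (pixel coordinates).

    Accepts the plain-text export with ``Track <id> ...`` headers followed by
    ``Point <n> <x> <y> <z> <t> <c>`` lines, or a whitespace/comma table with
    columns TID, PID, x, y, z, t. Frames (t) are converted to 0-based.
    """
    path = Path(path)
    tracks: dict[str, list[tuple[int, float, float]]] = {}
    current = None
    for raw in path.read_text().splitlines():
        line = raw.strip().replace(",", " ")
        if not line or line.startswith(("#", "MTrackJ", "Assembly", "Cluster",
                                        "Displaying", "Offset", "End")):
            continue
        parts = line.split()
        if parts[0].lower() == "track":
            current = parts[1]
            tracks.setdefault(current, [])
        elif parts[0].lower() == "point" and current is not None:
            x, y, t = float(parts[2]), float(parts[3]), float(parts[5])
            tracks[current].append((int(round(t)) - 1, x, y))
        elif len(parts) >= 6 and parts[0].replace(".", "").isdigit():
            tid = str(int(float(parts[0])))
            x, y, t = float(parts[2]), float(parts[3]), float(parts[5])
            tracks.setdefault(tid, []).append((int(round(t)) - 1, x, y))
    if not tracks:
        raise FormatError(f"no tracks parsed from {path}")
    out = []
    for tid, pts in tracks.items():
        pts.sort(key=lambda p: p[0])
        frames = [p[0] for p in pts]
        if len(set(frames)) != len(frames):
            raise FormatError(f"duplicate frames in MTrackJ track {tid}")
        out.append(Trajectory(
            np.array(frames),
            np.array([p[1] for p in pts]) * pixel_size_um,
            np.array([p[2] for p in pts]) * pixel_size_um,
            frame_interval_s=frame_interval_s,
            track_id=tid,
        ))
    return out


def read_phases(path: str | Path) -> dict[str, list[PhaseWindow]]:
    """Phase CSV (embryo_id, phase, first_frame, last_frame) → windows per embryo."""
    df = pd.read_csv(path, comment="#")
    out: dict[str, list[PhaseWindow]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["embryo_id"]), []).append(
            PhaseWindow(str(r["phase"]), int(r["first_frame"]), int(r["last_frame"]))
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full synthetic experiment run.

    ``groups`` maps group names to SceneConfig field overrides (e.g.
    ``{"control": {}, "atx2": {"depletion_mode": "atx2_like"}}``).
    """

    outdir: str = "results"
    seed: int = 0
    n_embryos: int = 10
    groups: dict[str, dict] = field(default_factory=lambda: {
        "control": {},
        "atx2_like": {"depletion_mode": "atx2_like"},
    })
    scene: dict = field(default_factory=dict)  # shared SceneConfig overrides
    phase: str = "AI"
    capture: dict = field(default_factory=dict)  # CaptureConfig overrides
    stages: tuple[str, ...] = ("simulate", "scatter", "track", "capture", "stats")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return yaml.safe_dump(d)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go and
        how verbosely we log do not affect the numbers)."""
        d = asdict(self)
        d.pop("outdir", None)
        d.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_csv_with_provenance(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# config_sha256={config.config_hash()} seed={config.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the requested stages of a synthetic experiment.

    simulate → per-group trajectory and ground-truth generation;
    scatter   → per-embryo weighted scatter profiles (mean, SD);
    track     → per-phase sperm-ring track metrics;
    capture   → capture-event classification and group contingency;
    stats     → normality-gated group comparisons of the scatter and track
                readouts.

    Returns a mapping of stage name to the primary CSV it wrote. Outputs are
    deterministic for a fixed config and seed.
    """
    from dataclasses import replace as _replace

    from .capture import CaptureConfig, capture_contingency, classify_tracks
    from .scatter import Punctum, scatter_profile
    from .stats import GroupedSamples, fisher_exact, report_comparisons
    from .synthetic import SceneConfig, phase_frame_windows, sample_puncta, \
        sample_streaming_trajectory, simulate_capture_scenario
    from .tracks import PhaseWindow, Trajectory, phase_metrics

    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    (outdir / "run_config.yaml").write_text(config.to_yaml())

    def scene_for(group: str, overrides: dict, embryo_index: int) -> SceneConfig:
        fields = dict(config.scene)
        fields.update(overrides)
        # stable per-embryo seed derived from the run seed
        h = int(hashlib.sha256(f"{config.seed}:{group}:{embryo_index}".encode())
                .hexdigest()[:8], 16) % (2 ** 31)
        fields["seed"] = h
        return SceneConfig(**fields)

    scenes = {
        group: [scene_for(group, ov, i) for i in range(config.n_embryos)]
        for group, ov in config.groups.items()
    }

    if "simulate" in config.stages:
        rows = []
        for group, cfgs in scenes.items():
            for i, sc in enumerate(cfgs):
                sperm, spindle = sample_streaming_trajectory(sc)
                for f, (p, q) in enumerate(zip(sperm, spindle)):
                    rows.append({"group": group, "embryo_id": f"{group}_{i}",
                                 "frame": f, "sperm_x_um": p[0], "sperm_y_um": p[1],
                                 "spindle_x_um": q[0], "spindle_y_um": q[1]})
        path = outdir / "trajectories.csv"
        _write_csv_with_provenance(pd.DataFrame(rows), path, config)
        outputs["simulate"] = path
        log.info("simulate: wrote %d trajectory rows", len(rows))

    scatter_rows = []
    if "scatter" in config.stages:
        for group, cfgs in scenes.items():
            for i, sc in enumerate(cfgs):
                dna, truth = sample_puncta(sc)
                puncta = [Punctum(tuple(t.position_um), t.true_intensity,
                                  t.true_intensity, t.true_multiplicity,
                                  t.true_multiplicity > 1) for t in truth]
                prof = scatter_profile(puncta, dna, config.phase, f"{group}_{i}")
                scatter_rows.append({"group": group, "embryo_id": prof.embryo_id,
                                     "phase": prof.phase,
                                     "n_weighted": prof.distances_um.size,
                                     "mean_um": prof.mean_um, "sd_um": prof.sd_um})
        path = outdir / "scatter_profiles.csv"
        _write_csv_with_provenance(pd.DataFrame(scatter_rows), path, config)
        outputs["scatter"] = path
        log.info("scatter: %d embryo profiles", len(scatter_rows))

    track_rows = []
    if "track" in config.stages:
        for group, cfgs in scenes.items():
            for i, sc in enumerate(cfgs):
                sperm, _ = sample_streaming_trajectory(sc)
                traj = Trajectory.from_points(sperm, sc.frame_interval_s,
                                              embryo_id=f"{group}_{i}")
                windows = [PhaseWindow(p, a, b) for p, a, b in phase_frame_windows(sc)]
                for m in phase_metrics(traj, windows):
                    track_rows.append({
                        "group": group, "embryo_id": traj.embryo_id,
                        "phase": m.phase, "max_x_disp_um": m.max_x_disp_um,
                        "max_y_disp_um": m.max_y_disp_um,
                        "net_displacement_um": m.net_displacement_um,
                        "path_length_um": m.path_length_um,
                        "max_avg_velocity_um_s": m.max_avg_velocity_um_s,
                        "duration_s": m.duration_s,
                    })
        path = outdir / "track_metrics.csv"
        _write_csv_with_provenance(pd.DataFrame(track_rows), path, config)
        outputs["track"] = path

    if "capture" in config.stages:
        cap_cfg = CaptureConfig(**config.capture)
        events_by_group = {}
        rows = []
        for group, cfgs in scenes.items():
            events = []
            for i, sc in enumerate(cfgs):
                sperm, spindle, _ = simulate_capture_scenario(sc)
                ev = classify_tracks(
                    Trajectory.from_points(sperm, sc.frame_interval_s),
                    Trajectory.from_points(spindle, sc.frame_interval_s),
                    cap_cfg, embryo_id=f"{group}_{i}",
                )
                events.append(ev)
                rows.append({"group": group, "embryo_id": ev.embryo_id,
                             "min_distance_um": ev.min_distance_um,
                             "classification": ev.classification,
                             "threshold_um": cap_cfg.threshold_um,
                             "stuck_window_frames": cap_cfg.stuck_window_frames,
                             "stuck_disp_um": cap_cfg.stuck_disp_um})
            events_by_group[group] = events
        path = outdir / "capture_events.csv"
        _write_csv_with_provenance(pd.DataFrame(rows), path, config)
        table = capture_contingency(events_by_group)
        tab_rows = [{"group": g, "captured": r[0], "not_captured": r[1]}
                    for g, r in zip(events_by_group, table)]
        _write_csv_with_provenance(pd.DataFrame(tab_rows),
                                   outdir / "capture_contingency.csv", config)
        outputs["capture"] = path
        if len(table) == 2:
            res = fisher_exact(table)
            log.info("capture: Fisher exact p=%.4g", res.p_value)

    if "stats" in config.stages and scatter_rows:
        df = pd.DataFrame(scatter_rows)
        comparisons = []
        for metric in ("mean_um", "sd_um"):
            comparisons.append(GroupedSamples(
                {g: sub[metric].to_numpy() for g, sub in df.groupby("group")},
                metric_name=f"scatter_{metric}", units="um",
            ))
        if track_rows:
            tdf = pd.DataFrame(track_rows)
            for metric in ("max_x_disp_um", "max_y_disp_um"):
                comparisons.append(GroupedSamples(
                    {g: sub[metric].to_numpy() for g, sub in tdf.groupby("group")},
                    metric_name=f"track_{metric}", units="um",
                ))
        report = report_comparisons(comparisons)
        path = outdir / "stats_report.tsv"
        header = f"# config_sha256={config.config_hash()} seed={config.seed}\n"
        with open(path, "w") as fh:
            fh.write(header)
            report.to_csv(fh, sep="\t", index=False)
        outputs["stats"] = path

    return outputs
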