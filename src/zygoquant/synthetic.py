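"""Ground-truthed synthetic meiotic zygotes: z-stacks and time-lapse tracks.

The generator emulates the imaging scenarios the downstream quantification
modules are built for, with full ground truth so every stage can be tested
without microscope data:

* a fixed-embryo z-stack scenario — an ellipsoid embryo containing a cohesive
  cloud of paternal-mitochondria puncta (plus brighter amorphous masses)
  around the sperm-DNA focus, a DNA channel, and a tubulin (spindle) channel;
* a live time-lapse scenario — 2-D tracks of the sperm contents (ER ring)
  and the nearly stationary meiotic spindle under three streaming regimes
  (jostling, short-axis rotation, long-axis rotation), with optional
  programmed spindle-capture events.

Streaming is modeled phenomenologically as regime-dependent kinematics, not
hydrodynamics: the pipeline only needs trajectories with controllable
displacement statistics. Depletion modes rescale streaming amplitude
(katanin/kinesin-13-like) or cloud dispersion (ataxin-2-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, PlacementError
from .geometry import EllipsoidDims

PHASE_ORDER = ("MI", "AI", "MII", "AII")

STREAMING_MODES = ("jostle", "short_axis", "long_axis")

CAPTURE_SCENARIOS = ("none", "stable", "transient")

#: (streaming amplitude multiplier, cloud dispersion multiplier) per depletion
#: mode. Katanin- and kinesin-13-like depletions increase streaming amplitude;
#: ataxin-2-like depletion disperses the mitochondria cloud; the double mode
#: compounds both. Control is the identity.
DEPLETION_MULTIPLIERS: dict[str, tuple[float, float]] = {
    "control": (1.0, 1.0),
    "mei1_like": (3.0, 1.0),
    "klp7_like": (3.0, 1.0),
    "atx2_like": (1.0, 3.0),
    "double_klp7_atx2": (3.0, 3.0),
}

#: Per-phase scaling of streaming amplitude. Movement of the sperm contents is
#: limited while the ER is sheet-like (metaphase) and increases when the ER
#: disperses (anaphase I); the kinesin-13-like mode overrides metaphase II to
#: stay elevated (excessive streaming persisting into MII).
PHASE_AMPLITUDE_FACTOR = {"MI": 0.3, "AI": 1.0, "MII": 0.4, "AII": 0.3}

_MAX_REJECTION_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic zygote scene.

    Physical defaults follow the imaging conditions the pipeline targets:
    65 nm pixels, 1 µm z-steps, 5 s frame interval, and a 50 µm × 25 µm
    ellipsoid embryo (semi-axes 25, 12.5, 12.5 µm).
    """

    embryo: EllipsoidDims = EllipsoidDims(25.0, 12.5, 12.5)
    pixel_size_um: float = 0.065
    z_step_um: float = 1.0
    frame_interval_s: float = 5.0
    n_puncta: int = 30
    n_masses: int = 4
    punctum_intensity_mean: float = 100.0
    punctum_intensity_cv: float = 0.2
    mass_intensity_factor: float = 3.0
    cloud_sigma_um: float = 1.0
    psf_sigma_um: float = 0.2
    background_level: float = 10.0
    noise_sd: float = 2.0
    streaming_mode: str = "jostle"
    streaming_amplitude_um_s: float = 0.15
    depletion_mode: str = "control"
    capture_scenario: str = "none"
    phase_schedule: tuple[tuple[str, float], ...] = (
        ("MI", 300.0),
        ("AI", 150.0),
        ("MII", 300.0),
        ("AII", 150.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "z_step_um", "frame_interval_s",
                     "cloud_sigma_um", "psf_sigma_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_puncta < 1:
            raise ConfigError("n_puncta must be >= 1")
        if self.mass_intensity_factor < 1:
            raise ConfigError("mass_intensity_factor must be >= 1")
        if self.streaming_amplitude_um_s < 0:
            raise ConfigError("streaming_amplitude_um_s must be >= 0")
        if self.streaming_mode not in STREAMING_MODES:
            raise ConfigError(f"unknown streaming_mode {self.streaming_mode!r}")
        if self.depletion_mode not in DEPLETION_MULTIPLIERS:
            raise ConfigError(f"unknown depletion_mode {self.depletion_mode!r}")
        if self.capture_scenario not in CAPTURE_SCENARIOS:
            raise ConfigError(f"unknown capture_scenario {self.capture_scenario!r}")
        if not self.phase_schedule:
            raise ConfigError("phase_schedule must be nonempty")
        phases = [p for p, _ in self.phase_schedule]
        if not _is_contiguous_subsequence(phases):
            raise ConfigError(
                f"phase_schedule {phases} is not a contiguous subsequence of "
                f"{PHASE_ORDER}"
            )
        for _, dur in self.phase_schedule:
            if dur <= 0:
                raise ConfigError("phase durations must be positive")


def _is_contiguous_subsequence(phases: Sequence[str]) -> bool:
    if any(p not in PHASE_ORDER for p in phases):
        return False
    if not phases:
        return False
    start = PHASE_ORDER.index(phases[0])
    return tuple(phases) == PHASE_ORDER[start:start + len(phases)]


@dataclass
class PunctumTruth:
    """Ground-truth record for one rendered focus."""

    position_um: np.ndarray  # (3,) image-frame coordinates, µm
    true_intensity: float
    true_multiplicity: int


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene."""

    dna_position_um: np.ndarray
    puncta: list[PunctumTruth]
    sperm_track: np.ndarray  # (n_frames, 2), embryo-frame µm
    spindle_track: np.ndarray  # (n_frames, 2)
    phase_windows: list[tuple[str, int, int]]  # (phase, first_frame, last_frame)
    capture_frame: Optional[int] = None
    embryo_center_um: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )  # embryo centre in image-frame coordinates


def apply_depletion_mode(config: SceneConfig) -> tuple[float, float]:
    """Return (streaming multiplier, cloud-sigma multiplier) for the config's mode."""
    try:
        return DEPLETION_MULTIPLIERS[config.depletion_mode]
    except KeyError:  # pragma: no cover - blocked by SceneConfig validation
        raise ConfigError(f"unknown depletion_mode {config.depletion_mode!r}")


def _inside_ellipsoid(p: np.ndarray, dims: EllipsoidDims, margin: float = 0.0) -> bool:
    a, b, c = dims.a_um - margin, dims.b_um - margin, dims.c_um - margin
    if min(a, b, c) <= 0:
        return False
    return (p[0] / a) ** 2 + (p[1] / b) ** 2 + (p[2] / c) ** 2 <= 1.0


def _clip_to_ellipse(p: np.ndarray, dims: EllipsoidDims, frac: float = 0.95) -> np.ndarray:
    """Radially project a 2-D point into the (frac-scaled) embryo mid-plane ellipse."""
    a, b = dims.a_um * frac, dims.b_um * frac
    r = (p[0] / a) ** 2 + (p[1] / b) ** 2
    if r <= 1.0:
        return p
    return p / math.sqrt(r)


def default_dna_position(config: SceneConfig) -> np.ndarray:
    """Sperm-DNA centroid in the embryo frame: offset toward the fertilisation
    pole (positive x, opposite the spindle)."""
    return np.array([0.5 * config.embryo.a_um, 0.0, 0.0])


def sample_puncta(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[PunctumTruth]]:
    """Sample the paternal-mitochondria cloud around the sperm DNA.

    Punctum positions are isotropic Gaussian displacements (sd =
    cloud_sigma_um × depletion multiplier) from the DNA centroid, rejection
    sampled into the embryo. Masses carry integer multiplicity ≥ 2 drawn with
    mean ``mass_intensity_factor`` and proportionally brighter intensity.

    Returns (dna_position_um, puncta) in the embryo frame.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    _, cloud_mult = apply_depletion_mode(config)
    sigma = config.cloud_sigma_um * cloud_mult
    dna = default_dna_position(config)
    margin = 2.0 * config.psf_sigma_um

    def _place() -> np.ndarray:
        for _ in range(_MAX_REJECTION_ATTEMPTS):
            p = dna + rng.normal(0.0, sigma, size=3)
            if _inside_ellipsoid(p, config.embryo, margin=margin):
                return p
        raise PlacementError(
            f"could not place punctum inside embryo after "
            f"{_MAX_REJECTION_ATTEMPTS} attempts (cloud_sigma_um={sigma})"
        )

    puncta: list[PunctumTruth] = []
    for _ in range(config.n_puncta):
        inten = config.punctum_intensity_mean * max(
            0.1, 1.0 + config.punctum_intensity_cv * rng.standard_normal()
        )
        puncta.append(PunctumTruth(_place(), inten, 1))
    for _ in range(config.n_masses):
        k = max(2, int(rng.poisson(config.mass_intensity_factor)))
        inten = k * config.punctum_intensity_mean * max(
            0.1, 1.0 + config.punctum_intensity_cv * rng.standard_normal()
        )
        puncta.append(PunctumTruth(_place(), inten, k))
    return dna, puncta


def _render_gaussian(
    channel: np.ndarray,
    center_vox: np.ndarray,
    sigma_vox: np.ndarray,
    amplitude: float,
) -> None:
    """Add a peak-normalised anisotropic 3-D Gaussian to ``channel`` in place.

    Rendered on a local patch of ±4 sigma around the centre.
    """
    lo = np.maximum(np.floor(center_vox - 4 * sigma_vox).astype(int), 0)
    hi = np.minimum(
        np.ceil(center_vox + 4 * sigma_vox).astype(int) + 1,
        np.array(channel.shape),
    )
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    q = (
        ((zz - center_vox[0]) / sigma_vox[0]) ** 2
        + ((yy - center_vox[1]) / sigma_vox[1]) ** 2
        + ((xx - center_vox[2]) / sigma_vox[2]) ** 2
    )
    channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-0.5 * q)


def simulate_zstack(config: SceneConfig):
    """Render a multi-channel z-stack of a fixed meiotic embryo.

    Channels are (mitochondria, dna, tubulin). Each punctum is a 3-D Gaussian
    of physical width ``psf_sigma_um`` scaled by its intensity; masses are
    rendered as ``k`` clustered overlapping Gaussians so their summed local
    intensity is about ``k`` times a single punctum. Additive background and
    Gaussian noise finish the image. Ground truth (image-frame coordinates,
    µm) is returned alongside.

    Returns ``(ImageStack, GroundTruth)``.
    """
    from .io import ImageStack  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    dims = config.embryo
    pad = 2.0  # µm of empty margin around the embryo
    extent = np.array([
        2 * dims.c_um + 2 * pad,  # z
        2 * dims.b_um + 2 * pad,  # y
        2 * dims.a_um + 2 * pad,  # x
    ])
    spacing = np.array([config.z_step_um, config.pixel_size_um, config.pixel_size_um])
    shape = np.ceil(extent / spacing).astype(int)
    center_vox = (shape - 1) / 2.0
    center_um = center_vox * spacing  # embryo centre in image coordinates

    def to_image_um(p_embryo: np.ndarray) -> np.ndarray:
        """Embryo-frame (x, y, z) µm → image-frame (x, y, z) µm."""
        return np.array([
            p_embryo[0] + center_um[2],
            p_embryo[1] + center_um[1],
            p_embryo[2] + center_um[0],
        ])

    def to_vox(p_image_um: np.ndarray) -> np.ndarray:
        """Image-frame (x, y, z) µm → voxel (z, y, x) index coordinates."""
        return np.array([
            p_image_um[2] / spacing[0],
            p_image_um[1] / spacing[1],
            p_image_um[0] / spacing[2],
        ])

    sigma_vox = np.array([
        config.psf_sigma_um / spacing[0],
        config.psf_sigma_um / spacing[1],
        config.psf_sigma_um / spacing[2],
    ])

    mito = np.zeros(tuple(shape), dtype=np.float64)
    dna_ch = np.zeros_like(mito)
    tub_ch = np.zeros_like(mito)

    dna_embryo, puncta = sample_puncta(config, rng)
    truth_puncta: list[PunctumTruth] = []
    for pt in puncta:
        pos_img = to_image_um(pt.position_um)
        if pt.true_multiplicity == 1:
            _render_gaussian(mito, to_vox(pos_img), sigma_vox, pt.true_intensity)
        else:
            # cluster of k sub-foci jittered by a fraction of the PSF width so
            # they overlap into one amorphous mass
            k = pt.true_multiplicity
            amp = pt.true_intensity / k
            for _ in range(k):
                jitter = rng.normal(0.0, 0.3 * config.psf_sigma_um, size=3)
                _render_gaussian(mito, to_vox(pos_img + jitter), sigma_vox, amp)
        truth_puncta.append(PunctumTruth(pos_img, pt.true_intensity, pt.true_multiplicity))

    dna_img = to_image_um(dna_embryo)
    _render_gaussian(dna_ch, to_vox(dna_img), sigma_vox * 3.0, 200.0)

    sperm_track, spindle_track = sample_streaming_trajectory(config, rng=rng)
    spindle_img = to_image_um(np.array([*spindle_track[0], 0.0]))
    _render_gaussian(tub_ch, to_vox(spindle_img), sigma_vox * 5.0, 150.0)

    voxels = np.stack([mito, dna_ch, tub_ch])
    voxels += config.background_level
    if config.noise_sd > 0:
        voxels += rng.normal(0.0, config.noise_sd, size=voxels.shape)
    np.clip(voxels, 0.0, None, out=voxels)

    stack = ImageStack(
        voxels=voxels.astype(np.float32),
        channel_names=("mitochondria", "dna", "tubulin"),
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
        frame_interval_s=config.frame_interval_s,
    )
    truth = GroundTruth(
        dna_position_um=dna_img,
        puncta=truth_puncta,
        sperm_track=sperm_track,
        spindle_track=spindle_track,
        phase_windows=phase_frame_windows(config),
        capture_frame=None,
        embryo_center_um=np.array([center_um[2], center_um[1], center_um[0]]),
    )
    return stack, truth


def phase_frame_windows(config: SceneConfig) -> list[tuple[str, int, int]]:
    """Frame windows (phase, first_frame, last_frame), inclusive, back to back."""
    windows = []
    first = 0
    for phase, dur_s in config.phase_schedule:
        n = max(1, int(round(dur_s / config.frame_interval_s)))
        windows.append((phase, first, first + n - 1))
        first += n
    return windows


def _n_frames(config: SceneConfig) -> int:
    return phase_frame_windows(config)[-1][2] + 1


def _phase_factors(config: SceneConfig) -> np.ndarray:
    """Per-frame streaming amplitude factor from the phase schedule."""
    factors = dict(PHASE_AMPLITUDE_FACTOR)
    if config.depletion_mode in ("klp7_like", "double_klp7_atx2"):
        factors["MII"] = 1.0  # elevated streaming persists into metaphase II
    out = np.empty(_n_frames(config))
    for phase, first, last in phase_frame_windows(config):
        out[first:last + 1] = factors[phase]
    return out


def _spindle_rest_position(config: SceneConfig) -> np.ndarray:
    return np.array([-0.8 * config.embryo.a_um, 0.0])


def sample_streaming_trajectory(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample 2-D sperm-content and spindle tracks for one time-lapse.

    Regimes (sperm track):

    * ``jostle`` — fixed-magnitude steps in seeded random directions
      (directions resampled near the boundary), i.e. random movement with no
      net direction;
    * ``short_axis`` — oscillation along y (projection of rotation about the
      long axis);
    * ``long_axis`` — orbit in the x–y plane (rotation about the short axis),
      producing long x excursions toward the spindle pole.

    Step size per frame is ``streaming_amplitude_um_s × frame_interval_s``
    scaled by the depletion-mode multiplier and the per-phase factor. The
    spindle track is nearly stationary at the left pole. All points lie
    inside the embryo mid-plane ellipse.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = _n_frames(config)
    stream_mult, _ = apply_depletion_mode(config)
    amp = config.streaming_amplitude_um_s * stream_mult
    dt = config.frame_interval_s
    factors = _phase_factors(config)
    dims = config.embryo

    start = np.array([0.5 * dims.a_um, 0.0])
    sperm = np.empty((n, 2))
    sperm[0] = start

    if config.streaming_mode == "jostle":
        for i in range(1, n):
            step = amp * dt * factors[i]
            pos = sperm[i - 1]
            if step == 0:
                sperm[i] = pos
                continue
            for _ in range(100):
                theta = rng.uniform(0.0, 2.0 * math.pi)
                cand = pos + step * np.array([math.cos(theta), math.sin(theta)])
                if (cand[0] / (0.95 * dims.a_um)) ** 2 + (
                    cand[1] / (0.95 * dims.b_um)
                ) ** 2 <= 1.0:
                    break
            else:  # pragma: no cover - start point is well inside
                cand = _clip_to_ellipse(pos, dims)
            sperm[i] = cand
    elif config.streaming_mode == "short_axis":
        radius = 0.6 * dims.b_um
        theta = 0.0
        for i in range(1, n):
            theta += amp * dt * factors[i] / radius
            jitter = rng.normal(0.0, 0.05 * amp * dt, size=2)
            pos = start + np.array([0.0, radius * math.sin(theta)]) + jitter
            sperm[i] = _clip_to_ellipse(pos, dims)
    else:  # long_axis
        rx, ry = 0.6 * dims.a_um, 0.6 * dims.b_um
        theta = 0.0
        for i in range(1, n):
            theta += amp * dt * factors[i] / rx
            jitter = rng.normal(0.0, 0.05 * amp * dt, size=2)
            pos = np.array([rx * math.cos(theta), ry * math.sin(theta)]) + jitter
            sperm[i] = _clip_to_ellipse(pos, dims)

    spindle = _spindle_rest_position(config) + np.cumsum(
        rng.normal(0.0, 0.02, size=(n, 2)), axis=0
    )
    spindle = np.array([_clip_to_ellipse(p, dims) for p in spindle])
    return sperm, spindle


def simulate_capture_scenario(
    config: SceneConfig,
    capture_distance_um: float = 4.0,
    threshold_um: float = 5.5,
) -> tuple[np.ndarray, np.ndarray, Optional[int]]:
    """Generate paired tracks with a programmed spindle-capture outcome.

    * ``stable`` — the sperm contents approach the spindle, cross below the
      capture threshold, and stop moving relative to it for the remainder.
    * ``transient`` — the track dips below threshold, departs above it, then
      re-approaches and sticks (transient capture followed by stable capture;
      the distance series crosses below the threshold exactly twice).
    * ``none`` — a streaming trajectory constrained to keep at least 8 µm
      centre-to-centre from the spindle.

    Returns ``(sperm_track, spindle_track, capture_frame)`` where
    ``capture_frame`` is the first frame of the final below-threshold episode
    (None for the ``none`` scenario).
    """
    rng = np.random.default_rng(config.seed)
    n = _n_frames(config)
    dims = config.embryo
    spindle_rest = _spindle_rest_position(config)

    if config.capture_scenario == "none":
        sperm, spindle = sample_streaming_trajectory(config, rng=rng)
        min_sep = 8.0
        if min_sep >= 2 * dims.a_um:
            raise ConfigError("embryo too small to hold an 8 µm exclusion zone")
        for i in range(n):
            rel = sperm[i] - spindle[i]
            d = float(np.hypot(*rel))
            if d < min_sep:
                direction = rel / d if d > 0 else np.array([1.0, 0.0])
                cand = _clip_to_ellipse(
                    spindle[i] + min_sep * direction, dims, frac=1.0
                )
                if float(np.hypot(*(cand - spindle[i]))) < min_sep:
                    # pushed point fell outside the embryo; place it on the
                    # exclusion circle toward the embryo centre instead
                    inward = -spindle[i] / float(np.hypot(*spindle[i]))
                    cand = spindle[i] + min_sep * inward
                sperm[i] = cand
        return sperm, spindle, None

    d_start = float(np.hypot(*(np.array([0.5 * dims.a_um, 0.0]) - spindle_rest)))
    if capture_distance_um >= threshold_um:
        raise ConfigError("capture distance must be below the threshold")
    if threshold_um >= d_start:
        raise ConfigError("threshold geometry impossible inside embryo")

    if config.capture_scenario == "stable":
        t_cap = int(0.6 * n)
        dist = np.empty(n)
        dist[:t_cap] = np.linspace(d_start, capture_distance_um, t_cap)
        dist[t_cap:] = capture_distance_um
        capture_frame = int(np.argmax(dist < threshold_um))
    else:  # transient then stable
        t1, t2, t3 = int(0.25 * n), int(0.5 * n), int(0.75 * n)
        dip = capture_distance_um + 0.5
        rise = threshold_um + 3.5
        dist = np.empty(n)
        dist[:t1] = np.linspace(d_start, dip, t1)
        dist[t1:t2] = np.linspace(dip, rise, t2 - t1)
        dist[t2:t3] = np.linspace(rise, capture_distance_um, t3 - t2)
        dist[t3:] = capture_distance_um
        below = dist < threshold_um
        # first frame of the final below-threshold episode
        last_above = np.nonzero(~below)[0][-1]
        capture_frame = int(last_above + 1)

    spindle = np.tile(spindle_rest, (n, 1)) + rng.normal(0.0, 0.01, size=(n, 2))
    sperm = np.empty((n, 2))
    stuck = np.zeros(n, dtype=bool)
    stuck[capture_frame:] = dist[capture_frame:] <= capture_distance_um
    for i in range(n):
        jitter_sd = 0.005 if stuck[i] else 0.05
        sperm[i] = spindle[i] + np.array([dist[i], 0.0]) + rng.normal(
            0.0, jitter_sd, size=2
        )
    # capture_frame reported against the rendered (jittered) distances:
    # first frame of the final below-threshold episode
    d_actual = np.hypot(*(sperm - spindle).T)
    above = np.nonzero(d_actual >= threshold_um)[0]
    capture_frame = int(above[-1] + 1) if above.size else 0
    return sperm, spindle, capture_frame


def depleted_config(config: SceneConfig, mode: str) -> SceneConfig:
    """Convenience: the same scene under a different depletion mode."""
    if mode not in DEPLETION_MULTIPLIERS:
        raise ConfigError(f"unknown depletion_mode {mode!r}")
    return replace(config, depletion_mode=mode)
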