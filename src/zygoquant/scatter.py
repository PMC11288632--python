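"""Paternal-mitochondria scatter statistic.

A fixed-embryo z-stack yields, per embryo, a multiplicity-weighted list of
punctum-to-sperm-DNA distances: each fluorescent focus contributes its 3-D
Euclidean distance to the DNA centroid once per "mitochondrion" it
represents. Distinct puncta count once; brighter amorphous masses are
assigned an integer multiplicity by dividing their background-corrected mean
ROI intensity by the embryo's average punctum intensity and rounding
(half-up, floor 1). The per-embryo mean and sample standard deviation of the
weighted distances are the scatter readouts compared across treatments.

Quantification applies to anaphase I, metaphase II and anaphase II embryos;
metaphase I is excluded because it immediately follows fertilisation, before
scattering can manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label, regionprops

from .errors import (
    DegenerateEmbryoError,
    ExcludedPhaseError,
    NoDataError,
    NoSignalError,
)
from .geometry import round_half_up
from .intensity import ROISpec, background_correct, measure_roi_mean, roi_diameter_px

QUANTIFIABLE_PHASES = ("AI", "MII", "AII")

#: A connected fluorescent region whose in-plane area exceeds this many ROI
#: areas is treated as an amorphous mass and tiled with multiple ROIs.
MASS_AREA_FACTOR = 3.0


@dataclass(frozen=True)
class Punctum:
    """A measured mitochondrial focus."""

    position_um: tuple[float, float, float]
    raw_mean: float
    corrected_mean: float
    multiplicity: int = 1
    is_mass: bool = False


@dataclass
class ScatterProfile:
    """Per-embryo weighted distance distribution with its summaries."""

    embryo_id: str
    phase: str
    distances_um: np.ndarray
    mean_um: float
    sd_um: float
    degenerate: bool = False  # single-observation profile (SD undefined → 0)


@dataclass(frozen=True)
class DetectionParams:
    """Tunables for automated punctum detection."""

    smooth_sigma_um: float = 0.1
    threshold_abs: float | None = None  # absolute floor; default: bg + 5×noise
    roi_diameter_um: float = 18 * 0.065


def detect_puncta(
    volume: np.ndarray,
    pixel_size_um: float,
    z_step_um: float,
    params: DetectionParams = DetectionParams(),
) -> np.ndarray:
    """Detect candidate puncta in one channel volume (z, y, x).

    Local maxima of the Gaussian-smoothed volume above an absolute intensity
    floor; maxima closer than one ROI diameter (3-D physical distance) are
    merged into the brighter one. Returns an (N, 3) array of (x, y, z)
    positions in µm from the image origin.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.size == 0 or float(vol.max()) <= 0:
        raise NoSignalError("channel contains no signal")

    sigma_vox = (
        params.smooth_sigma_um / z_step_um,
        params.smooth_sigma_um / pixel_size_um,
        params.smooth_sigma_um / pixel_size_um,
    )
    smoothed = ndi.gaussian_filter(vol, sigma=sigma_vox)
    if params.threshold_abs is None:
        bg = float(np.median(smoothed))
        floor = bg + 5.0 * float(smoothed.std())
    else:
        floor = params.threshold_abs
    coords = peak_local_max(smoothed, threshold_abs=floor, exclude_border=False)
    if coords.size == 0:
        return np.empty((0, 3))

    spacing = np.array([z_step_um, pixel_size_um, pixel_size_um])
    pos_um = coords * spacing  # (z, y, x) µm
    intens = smoothed[tuple(coords.T)]
    order = np.argsort(intens)[::-1]
    merge_radius = roi_diameter_px(pixel_size_um, params.roi_diameter_um) * pixel_size_um
    kept: list[int] = []
    for idx in order:
        p = pos_um[idx]
        if all(np.linalg.norm(p - pos_um[j]) >= merge_radius for j in kept):
            kept.append(idx)
    out = pos_um[kept][:, ::-1]  # → (x, y, z) µm
    return out


def punctum_multiplicity(
    mass_corrected_mean: float, mean_of_punctum_corrected_means: float
) -> int:
    """Integer multiplicity of a mass ROI relative to the average punctum.

    The corrected mass mean is divided by the embryo's average corrected
    punctum mean; the ratio is rounded half-up with a floor of 1 (a measured
    fluorescent region represents at least one mitochondrion). Negative
    corrected means are clipped to zero before rounding.
    """
    if mean_of_punctum_corrected_means <= 0:
        raise DegenerateEmbryoError(
            "average punctum intensity must be positive to normalise masses"
        )
    ratio = max(0.0, mass_corrected_mean) / mean_of_punctum_corrected_means
    return max(1, round_half_up(ratio))


def distance_to_dna(
    punctum_position_um, dna_position_um
) -> float:
    """3-D Euclidean distance (µm) between a punctum and the sperm DNA."""
    p = np.asarray(punctum_position_um, dtype=float)
    d = np.asarray(dna_position_um, dtype=float)
    if p.shape != d.shape:
        raise ValueError(f"position shapes differ: {p.shape} vs {d.shape}")
    return float(np.linalg.norm(p - d))


def scatter_profile(
    puncta: list[Punctum],
    dna_position_um,
    phase: str,
    embryo_id: str = "",
) -> ScatterProfile:
    """Multiplicity-weighted distance distribution for one embryo.

    Each punctum contributes its DNA distance ``multiplicity`` times. The
    summary mean uses the weighted list; SD is the sample standard deviation
    (n−1). A single-observation profile is flagged degenerate with SD 0.
    """
    if phase == "MI":
        raise ExcludedPhaseError(
            "metaphase I embryos are excluded from scatter quantification"
        )
    if phase not in QUANTIFIABLE_PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {QUANTIFIABLE_PHASES}")
    if not puncta:
        raise NoDataError("no puncta to profile")
    weighted: list[float] = []
    for p in puncta:
        d = distance_to_dna(p.position_um, dna_position_um)
        weighted.extend([d] * int(p.multiplicity))
    arr = np.asarray(weighted, dtype=float)
    degenerate = arr.size < 2
    sd = 0.0 if degenerate else float(arr.std(ddof=1))
    return ScatterProfile(
        embryo_id=embryo_id,
        phase=phase,
        distances_um=arr,
        mean_um=float(arr.mean()),
        sd_um=sd,
        degenerate=degenerate,
    )


@dataclass
class EmbryoQuantification:
    """Full automated readout of one embryo stack."""

    puncta: list[Punctum]
    profile: ScatterProfile
    background_mean: float


def _auto_background_position(smoothed_plane: np.ndarray, d_px: int) -> tuple[int, int]:
    """Centre (x, y) of the in-plane disk with minimal local mean intensity."""
    local_mean = ndi.uniform_filter(smoothed_plane, size=d_px)
    r = d_px // 2 + 1
    interior = local_mean[r:-r, r:-r]
    iy, ix = np.unravel_index(np.argmin(interior), interior.shape)
    return ix + r, iy + r


def quantify_stack(
    stack,
    dna_position_um,
    phase: str,
    embryo_id: str = "",
    params: DetectionParams = DetectionParams(),
    embryo_mask: np.ndarray | None = None,
) -> EmbryoQuantification:
    """End-to-end scatter quantification of a mitochondria-channel z-stack.

    Detects foci, measures each with the standard disk ROI on its sharpest
    plane, corrects by an automatically placed background ROI (the in-embryo
    region with least mitochondrial signal), classifies amorphous masses by
    connected-region area (> ``MASS_AREA_FACTOR`` ROI areas), tiles masses
    with additional ROIs, assigns multiplicities, and returns the weighted
    scatter profile. Detections outside ``embryo_mask`` (z, y, x boolean, if
    given) are discarded — e.g. fluorescence from sperm outside the embryo.
    """
    vol = stack.channel("mitochondria").astype(float)
    px = stack.pixel_size_um
    dz = stack.z_step_um
    d_px = roi_diameter_px(px, params.roi_diameter_um)

    positions = detect_puncta(vol, px, dz, params)
    if embryo_mask is not None:
        keep = []
        for p in positions:
            iz = int(round(p[2] / dz))
            iy = int(round(p[1] / px))
            ix = int(round(p[0] / px))
            iz = np.clip(iz, 0, embryo_mask.shape[0] - 1)
            iy = np.clip(iy, 0, embryo_mask.shape[1] - 1)
            ix = np.clip(ix, 0, embryo_mask.shape[2] - 1)
            if embryo_mask[iz, iy, ix]:
                keep.append(p)
        positions = np.asarray(keep) if keep else np.empty((0, 3))
    if positions.shape[0] == 0:
        raise NoDataError("no puncta detected inside the embryo")

    # background ROI: darkest local region of the median plane
    sigma_vox = (0, params.smooth_sigma_um / px, params.smooth_sigma_um / px)
    smoothed = ndi.gaussian_filter(vol, sigma=sigma_vox)
    mid = vol.shape[0] // 2
    bx, by = _auto_background_position(smoothed[mid], d_px)
    bg = measure_roi_mean(vol[mid], ROISpec(center=(bx, by), diameter_px=d_px))

    # mass classification from connected regions above a global floor
    floor = float(np.median(smoothed)) + 3.0 * float(smoothed.std())
    labels = label(smoothed > floor)
    roi_area_px = np.pi * (d_px / 2.0) ** 2
    mass_labels = set()
    area_by_label = {}
    for region in regionprops(labels):
        # in-plane footprint area: voxel count / z extent
        zextent = region.bbox[3] - region.bbox[0]
        area = region.area / max(1, zextent)
        area_by_label[region.label] = area
        if area > MASS_AREA_FACTOR * roi_area_px:
            mass_labels.add(region.label)

    puncta: list[Punctum] = []
    mass_records: list[tuple[tuple[float, float, float], float]] = []
    for p in positions:
        ix, iy, iz = int(round(p[0] / px)), int(round(p[1] / px)), int(round(p[2] / dz))
        iz = int(np.clip(iz, 0, vol.shape[0] - 1))
        lab = labels[iz, min(iy, labels.shape[1] - 1), min(ix, labels.shape[2] - 1)]
        try:
            m = measure_roi_mean(vol[iz], ROISpec(center=(p[0] / px, p[1] / px), diameter_px=d_px))
        except Exception:
            continue  # focus too close to the image border to measure
        corrected = background_correct(m, bg)
        if lab in mass_labels:
            mass_records.append((tuple(p), corrected))
        else:
            puncta.append(Punctum(tuple(p), m.mean_intensity, corrected, 1, False))

    if not puncta and not mass_records:
        raise NoDataError("no measurable puncta")
    if puncta:
        punctum_avg = float(np.mean([p.corrected_mean for p in puncta]))
    else:
        raise DegenerateEmbryoError("no distinct puncta to normalise masses against")
    for pos, corrected in mass_records:
        mult = punctum_multiplicity(corrected, punctum_avg)
        puncta.append(Punctum(pos, corrected + bg.mean_intensity, corrected, mult, True))

    profile = scatter_profile(puncta, dna_position_um, phase, embryo_id)
    return EmbryoQuantification(puncta=puncta, profile=profile, background_mean=bg.mean_intensity)
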