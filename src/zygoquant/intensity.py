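"""ROI-based mean fluorescence, background correction, and intensity ratios.

Conventions: 0-based pixel indexing, (x, y) pixel coordinates, physical
coordinates in µm from the image origin. A pixel belongs to a disk ROI iff
its centre lies strictly within the radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.draw import polygon as _sk_polygon

from .errors import RoiError
from .geometry import round_half_up

#: Default ROI diameter in µm. At the reference 65 nm pixel size this is the
#: 18-pixel-diameter circle used to cover one mitochondrial punctum.
DEFAULT_ROI_DIAMETER_UM = 18 * 0.065


def roi_diameter_px(pixel_size_um: float, roi_diameter_um: float = DEFAULT_ROI_DIAMETER_UM) -> int:
    """ROI diameter converted from µm to pixels for a given calibration."""
    return max(1, round_half_up(roi_diameter_um / pixel_size_um))


@dataclass(frozen=True)
class ROISpec:
    """A disk or polygon region of interest on one image plane."""

    shape: str = "disk"  # "disk" | "polygon"
    center: Optional[tuple[float, float]] = None  # (x, y), pixels
    vertices: Optional[Sequence[tuple[float, float]]] = None  # polygon (x, y)
    diameter_px: float = 18.0
    z_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "polygon"):
            raise RoiError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "disk":
            if self.center is None:
                raise RoiError("disk ROI requires a center")
            if self.diameter_px < 1:
                raise RoiError("diameter_px must be >= 1")
        elif self.vertices is None or len(self.vertices) < 3:
            raise RoiError("polygon ROI requires >= 3 vertices")


@dataclass(frozen=True)
class RoiMeasurement:
    """Mean intensity over an ROI, with the pixel count it covers."""

    mean_intensity: float
    n_pixels: int
    corrected_intensity: Optional[float] = None


def roi_mask(plane_shape: tuple[int, int], roi: ROISpec) -> np.ndarray:
    """Boolean pixel mask of the ROI on a (ny, nx) plane.

    Raises :class:`RoiError` if the ROI extends beyond the image bounds or
    covers no pixel centre.
    """
    ny, nx = plane_shape
    mask = np.zeros((ny, nx), dtype=bool)
    if roi.shape == "disk":
        cx, cy = roi.center
        r = roi.diameter_px / 2.0
        if cx - r < -0.5 or cy - r < -0.5 or cx + r > nx - 0.5 or cy + r > ny - 0.5:
            raise RoiError(
                f"disk ROI (center=({cx}, {cy}), d={roi.diameter_px}px) extends "
                f"beyond a {nx}x{ny} image"
            )
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        yy, xx = np.mgrid[max(y0, 0):min(y1, ny), max(x0, 0):min(x1, nx)]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 < r ** 2
        mask[max(y0, 0):min(y1, ny), max(x0, 0):min(x1, nx)] = inside
    else:
        verts = np.asarray(roi.vertices, dtype=float)
        if (verts < -0.5).any() or (verts[:, 0] > nx - 0.5).any() or (
            verts[:, 1] > ny - 0.5
        ).any():
            raise RoiError("polygon ROI extends beyond the image")
        rr, cc = _sk_polygon(verts[:, 1], verts[:, 0], shape=(ny, nx))
        mask[rr, cc] = True
    if not mask.any():
        raise RoiError("ROI covers no pixel centre")
    return mask


def measure_roi_mean(plane: np.ndarray, roi: ROISpec) -> RoiMeasurement:
    """Arithmetic mean of the pixels whose centres fall inside the ROI."""
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise RoiError(f"expected a 2-D image plane, got ndim={plane.ndim}")
    mask = roi_mask(plane.shape, roi)
    vals = plane[mask]
    return RoiMeasurement(mean_intensity=float(vals.mean()), n_pixels=int(mask.sum()))


def background_correct(
    measurement: RoiMeasurement | float, background: RoiMeasurement | float
) -> float:
    """Signal mean minus background mean. Negative results are retained."""
    m = measurement.mean_intensity if isinstance(measurement, RoiMeasurement) else float(measurement)
    b = background.mean_intensity if isinstance(background, RoiMeasurement) else float(background)
    return m - b


def chromosome_to_cytoplasm_ratio(chrom_mean: float, cyto_mean: float) -> float:
    """Ratio of chromosomal to cytoplasmic mean fluorescence (e.g. GFP::BAF-1)."""
    if cyto_mean <= 0:
        raise ZeroDivisionError(
            f"cytoplasmic mean must be positive, got {cyto_mean}"
        )
    return chrom_mean / cyto_mean


def oocyte_depletion_intensity(
    plane: np.ndarray, cytoplasm_roi: ROISpec, off_specimen_roi: ROISpec
) -> float:
    """Cytoplasmic mean corrected by an off-specimen (no-worm) area.

    Used to compare depletion treatments by residual fluorescence. The two
    ROIs must be disjoint.
    """
    plane = np.asarray(plane)
    m_cyto = roi_mask(plane.shape, cytoplasm_roi)
    m_off = roi_mask(plane.shape, off_specimen_roi)
    if (m_cyto & m_off).any():
        raise RoiError("cytoplasm and off-specimen ROIs overlap")
    return float(plane[m_cyto].mean() - plane[m_off].mean())
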