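"""Frame-to-diameter extraction: threshold, clean, ellipse-fit, calibrate.

Pipeline per frame: convert to 8-bit grayscale, binarize the region of
interest at a fixed gray-level threshold (default 70; the lumen is
hypoechoic, so lumen pixels fall strictly below it), keep the largest
4-connected component with interior holes filled, fit an ellipse from the
second-order moments of the pixel set (axes rescaled so the ellipse area
equals the pixel count, the convention of common image-analysis tools), and
convert the minor axis to mm.

When the fixed threshold leaves a degenerate region (< 5 pixels) the frame
is retried with an automatic Otsu threshold computed inside the ROI and the
sample is flagged ``fallback_threshold``; if that also fails the sample is
flagged ``missing`` and linearly interpolated from its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigError, DegenerateRegionError, PipelineError
from .types import (Condition, DiameterSeries, ImageSequence,
                    FLAG_OK, FLAG_FALLBACK, FLAG_MISSING)

__all__ = [
    "ROI",
    "EllipseFit",
    "DEFAULT_THRESHOLD",
    "to_grayscale8",
    "binarize",
    "clean_mask",
    "fit_ellipse",
    "minor_diameter_mm",
    "equivalent_diameter_mm",
    "extract_series",
]

#: Fixed binarization gray level used for most frames.
DEFAULT_THRESHOLD = 70


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest; half-open [min, max) pixel indices."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise ConfigError(f"empty ROI {self}")
        if self.row_min < 0 or self.col_min < 0:
            raise ConfigError(f"ROI has negative indices: {self}")

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.row_max > shape[0] or self.col_max > shape[1]:
            raise ConfigError(f"ROI {self} exceeds frame shape {shape}")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_min, self.row_max),
                slice(self.col_min, self.col_max))

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ROI":
        return cls(0, shape[0], 0, shape[1])


@dataclass
class EllipseFit:
    """Moment-based ellipse: area-preserving axes in pixels."""

    center_px: tuple[float, float]
    major_px: float
    minor_px: float
    angle_deg: float
    area_px2: float


def to_grayscale8(frame) -> np.ndarray:
    """Convert an image of any depth/channel count to 8-bit grayscale.

    Channels are averaged with equal weights.  Inputs deeper than 8 bits
    (or floating point) are linearly rescaled from their own min/max range
    to [0, 255]; 8-bit grayscale input passes through unchanged.
    """
    arr = np.asarray(frame)
    if arr.size == 0:
        raise ConfigError("empty image")
    if arr.ndim == 3:
        flat = arr.astype(float).mean(axis=2)
    elif arr.ndim == 2:
        flat = arr.astype(float)
    else:
        raise ConfigError(f"expected 2-D or 2-D+channels image, got ndim={arr.ndim}")

    if arr.dtype == np.uint8:
        # channel average of 8-bit data needs no range rescale
        return np.clip(np.rint(flat), 0, 255).astype(np.uint8)
    lo, hi = flat.min(), flat.max()
    if hi == lo:
        return np.zeros(flat.shape, dtype=np.uint8)
    return np.clip(np.rint((flat - lo) * (255.0 / (hi - lo))), 0, 255).astype(np.uint8)


def binarize(frame8: np.ndarray, roi: ROI,
             threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Lumen mask: pixels strictly below ``threshold`` and inside the ROI."""
    frame8 = np.asarray(frame8)
    roi.check_within(frame8.shape)
    mask = np.zeros(frame8.shape, dtype=bool)
    sl = roi.slices
    mask[sl] = frame8[sl] < threshold
    return mask


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 4-connected component and fill interior holes."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask)       # default structure = 4-connectivity
    if n == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel())[1:]
    largest = np.argmax(sizes) + 1
    return ndimage.binary_fill_holes(labels == largest)


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Fit an ellipse to a binary region from its second-order moments.

    Orientation and axis ratio come from the eigen-decomposition of the
    central second-moment matrix of the pixel set; the axes are then scaled
    so that pi * (major/2) * (minor/2) equals the pixel count exactly.
    """
    pts = np.argwhere(mask)
    if pts.shape[0] < 5:
        raise DegenerateRegionError(
            f"region has {pts.shape[0]} pixels; need at least 5")
    n = pts.shape[0]
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred / n          # [[m_rr, m_rc], [m_rc, m_cc]]
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12)
    # semi-axis of an ideal filled ellipse relates to its moment as a = 2*sqrt(lambda)
    semi_minor, semi_major = 2.0 * np.sqrt(evals)
    ratio = semi_major / semi_minor
    semi_major = np.sqrt(n * ratio / np.pi)
    semi_minor = np.sqrt(n / (ratio * np.pi))
    vr, vc = evecs[:, 1]                   # eigenvector of the major axis
    angle_deg = float(np.degrees(np.arctan2(vr, vc))) % 180.0
    return EllipseFit(center_px=(float(centroid[0]), float(centroid[1])),
                      major_px=float(2.0 * semi_major),
                      minor_px=float(2.0 * semi_minor),
                      angle_deg=angle_deg,
                      area_px2=float(n))


def minor_diameter_mm(fit: EllipseFit, pixel_spacing_mm: float) -> float:
    """Short-axis diameter in mm: minor axis times the pixel spacing."""
    if pixel_spacing_mm <= 0:
        raise ConfigError("pixel_spacing_mm must be positive")
    return fit.minor_px * pixel_spacing_mm


def equivalent_diameter_mm(fit: EllipseFit, pixel_spacing_mm: float) -> float:
    """Diameter of the circle with the same area as the fitted region (mm)."""
    if pixel_spacing_mm <= 0:
        raise ConfigError("pixel_spacing_mm must be positive")
    return 2.0 * np.sqrt(fit.area_px2 / np.pi) * pixel_spacing_mm


def _measure_frame(frame8, roi, threshold, pixel_spacing_mm, diameter_mode):
    mask = clean_mask(binarize(frame8, roi, threshold))
    fit = fit_ellipse(mask)
    if diameter_mode == "equivalent_circle":
        return equivalent_diameter_mm(fit, pixel_spacing_mm)
    return minor_diameter_mm(fit, pixel_spacing_mm)


def extract_series(seq: ImageSequence, roi: ROI | None = None,
                   threshold: float = DEFAULT_THRESHOLD,
                   diameter_mode: str = "minor_axis",
                   participant_id: str = "", condition=None,
                   repetition: int = 0) -> DiameterSeries:
    """Run the full per-frame pipeline over an image sequence.

    ``diameter_mode`` is ``"minor_axis"`` (default) or ``"equivalent_circle"``.
    Frames where the fixed threshold fails fall back to an Otsu threshold
    inside the ROI (flag ``fallback_threshold``); frames that still fail are
    flagged ``missing`` and interpolated linearly between valid neighbours
    (edge values held at the boundaries).
    """
    if len(seq) == 0:
        raise ConfigError("image sequence is empty")
    if diameter_mode not in ("minor_axis", "equivalent_circle"):
        raise ConfigError(f"unknown diameter_mode {diameter_mode!r}")
    roi = roi or ROI.full(seq.frame_shape)
    roi.check_within(seq.frame_shape)

    values = np.full(len(seq), np.nan)
    flags = []
    for i in range(len(seq)):
        frame8 = to_grayscale8(seq.frames[i])
        try:
            values[i] = _measure_frame(frame8, roi, threshold,
                                       seq.pixel_spacing_mm, diameter_mode)
            flags.append(FLAG_OK)
            continue
        except DegenerateRegionError:
            pass
        try:
            roi_pixels = frame8[roi.slices]
            otsu = threshold_otsu(roi_pixels)
            values[i] = _measure_frame(frame8, roi, otsu,
                                       seq.pixel_spacing_mm, diameter_mode)
            flags.append(FLAG_FALLBACK)
        except (DegenerateRegionError, ValueError):
            flags.append(FLAG_MISSING)

    valid = ~np.isnan(values)
    if not valid.any():
        raise PipelineError("segmentation failed on every frame of the sequence")
    if not valid.all():
        idx = np.arange(len(values))
        values[~valid] = np.interp(idx[~valid], idx[valid], values[valid])

    cond = Condition.coerce(condition) if condition is not None else None
    return DiameterSeries(values, participant_id=participant_id, condition=cond,
                          repetition=repetition, quality_flags=flags)
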