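"""Shear-wave elastography quantification.

Tissue stiffness in SWE is expressed as an elastic (Young's) modulus
E = S/e in kPa — stress over strain; harder tissue has a higher modulus.
This module quantifies a modulus map around an outlined lesion: the
"shell" is a ring of stated physical width (typically 1 or 2 mm)
immediately outside the lesion boundary, over which Emax / Emean / Emin /
Esd are computed. A shell stiffer than the lesion interior is the
quantitative "hard ring sign". Skin thickness is measured from B-mode
images column-by-column (A-line analysis): the entry echo and the
dermis–subcutis interface are the two strongest axial gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Image2D

__all__ = [
    "ElasticityMap",
    "LesionMask",
    "ModulusStats",
    "shell_ring",
    "modulus_stats",
    "elastic_modulus",
    "relative_difference",
    "measure_thickness",
    "average_repeats",
    "DetectionError",
]


class DetectionError(RuntimeError):
    """Raised when interface detection fails (e.g. featureless image)."""


@dataclass(frozen=True)
class ElasticityMap:
    """2-D elastic-modulus field in kPa with isotropic pixel spacing (mm/px)."""

    values: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.all(np.isfinite(arr)):
            raise ValueError("modulus values contain NaN or Inf")
        if np.any(arr <= 0):
            raise ValueError("elastic moduli must be strictly positive (kPa)")
        object.__setattr__(self, "values", arr)
        sp = float(self.pixel_spacing)
        if not np.isfinite(sp) or sp <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        object.__setattr__(self, "pixel_spacing", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class LesionMask:
    """Boolean region of interest, same shape as its modulus map."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.dtype != np.bool_:
            arr = arr.astype(bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ModulusStats:
    """Summary statistics of the elastic modulus over a region, in kPa."""

    emax: float
    emean: float
    emin: float
    esd: float
    n_pixels: int


def shell_ring(mask: LesionMask, width_mm: float, spacing: float) -> LesionMask:
    """Ring of pixels within ``width_mm`` (Euclidean, mm) outside the mask.

    The ring contains every pixel not in the mask whose Euclidean distance
    to the nearest mask pixel is at most ``width_mm / spacing`` pixels
    (real-valued threshold, no rounding). Always disjoint from the input
    mask and clipped to the image.
    """
    if width_mm <= 0:
        raise ValueError(f"width_mm must be positive, got {width_mm}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    m = mask.mask
    if not m.any():
        raise ValueError("shell_ring requires a non-empty lesion mask")
    # distance from each background pixel to the nearest mask pixel (exact EDT)
    dist = ndimage.distance_transform_edt(~m)
    ring = (~m) & (dist <= width_mm / spacing)
    return LesionMask(ring)


def modulus_stats(emap: ElasticityMap, roi: LesionMask) -> ModulusStats:
    """Emax / Emean / Emin / Esd over the ROI pixels.

    Esd is the sample standard deviation (denominator n−1); a single-pixel
    ROI reports Esd = 0.
    """
    if emap.shape != roi.shape:
        raise ValueError(f"shape mismatch: map {emap.shape} vs roi {roi.shape}")
    vals = emap.values[roi.mask]
    if vals.size == 0:
        raise ValueError("modulus_stats requires a non-empty ROI")
    esd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ModulusStats(
        emax=float(vals.max()),
        emean=float(vals.mean()),
        emin=float(vals.min()),
        esd=esd,
        n_pixels=int(vals.size),
    )


def elastic_modulus(stress: float, strain: float) -> float:
    """Young's modulus E = S/e (stress over strain), same units as stress."""
    if strain == 0:
        raise ZeroDivisionError("elastic modulus undefined for zero strain (E = S/e)")
    return stress / strain


def relative_difference(e_lesion: float, e_control: float) -> float:
    """Signed relative modulus difference of lesion vs control skin, in percent."""
    if e_control <= 0:
        raise ValueError(f"control modulus must be positive, got {e_control}")
    return 100.0 * (e_lesion - e_control) / e_control


def measure_thickness(
    bmode: Image2D,
    column_range: tuple[int, int] | None = None,
    smooth_width: int = 5,
    min_thickness_mm: float = 0.5,
) -> float:
    """Dermal thickness (mm) from a B-mode image by A-line gradient analysis.

    Each column is smoothed with a centred moving average of ``smooth_width``
    pixels; the two largest-magnitude extrema of the axial derivative,
    at least ``min_thickness_mm`` apart, are taken as the entry echo and the
    dermis–subcutis interface. The reported thickness is the median over
    columns of the interface separation times the pixel spacing.

    Raises
    ------
    DetectionError
        If no column exhibits two detectable interfaces (e.g. a constant
        image).
    """
    spacing = bmode.require_spacing()
    a = bmode.pixels
    h, w = a.shape
    if column_range is None:
        cols = range(w)
    else:
        lo, hi = column_range
        if not (0 <= lo < hi <= w):
            raise ValueError(f"invalid column_range {column_range} for width {w}")
        cols = range(lo, hi)
    min_px = int(np.ceil(min_thickness_mm / spacing))
    if h < 2 * min_px:
        raise ValueError("image too short for the requested minimum thickness")
    scale = float(np.ptp(a))
    tiny = 1e-9 * (scale + 1.0)

    # Direct (non-recursive) moving average with edge padding: outputs at
    # positions with identical local input patterns are bitwise equal, so
    # gradient-plateau ties resolve identically at both interfaces.
    k = int(smooth_width)
    if k < 1:
        raise ValueError(f"smooth_width must be >= 1, got {smooth_width}")
    kernel = np.full(k, 1.0 / k)
    pad_lo, pad_hi = k // 2, k - 1 - k // 2

    per_column: list[float] = []
    for c in cols:
        padded = np.pad(a[:, c], (pad_lo, pad_hi), mode="edge")
        line = np.convolve(padded, kernel, mode="valid")
        grad = np.abs(np.gradient(line))
        i1 = int(np.argmax(grad))
        if grad[i1] <= tiny:
            continue
        idx = np.arange(h)
        far = np.abs(idx - i1) >= min_px
        if not far.any():
            continue
        masked = np.where(far, grad, -np.inf)
        i2 = int(np.argmax(masked))
        if masked[i2] <= tiny:
            continue
        per_column.append(abs(i2 - i1) * spacing)
    if not per_column:
        raise DetectionError("fewer than two detectable interfaces in every column")
    return float(np.median(per_column))


def average_repeats(values) -> float:
    """Mean of exactly three repeated measurements of the same site."""
    vals = np.asarray(values, dtype=np.float64)
    if vals.shape != (3,):
        raise ValueError(f"expected exactly 3 measurements, got shape {vals.shape}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("measurements must be finite")
    return float(vals.mean())
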