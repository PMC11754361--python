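"""Mean-fluorescence-intensity statistics and signal-to-background ratios.

The workflow this mirrors: a region of interest (ROI) is drawn on the white
light image of a specimen, transferred to the co-registered infrared (IR)
image, and the mean fluorescence intensity (MFI) of the ROI pixels is read
out in 8-bit arbitrary units. Ratios of ROI means — tumor over background
(TBR) or tumor over any reference region (SBR) — are the contrast measure;
a ratio >= 3 delineates tumor clearly, 1.5-3 is suboptimal, < 1.5 is
insufficient for intraoperative guidance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely

from fgsquant.exceptions import EmptyRoiError, FormatError, UndefinedRatioError
from fgsquant.imgio import rasterize_polygon

RATIO_NAMES = ("TBR", "SBR_1cm", "SBR_3cm", "SBR_tumorbed", "tumor_to_peritumoral")

#: Rec. 709 luma weights used to collapse RGB exports to one intensity channel.
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class MFIStats:
    """Intensity statistics over the rasterized ROI pixels (population SD)."""

    mean: float
    minimum: float
    maximum: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("MFIStats requires minimum <= mean <= maximum")
        if self.sd < 0 or self.n_pixels < 1:
            raise ValueError("MFIStats requires sd >= 0 and n_pixels >= 1")


@dataclass(frozen=True)
class RatioResult:
    """A named MFI ratio and its adequacy class for tumor delineation."""

    name: str
    value: float
    adequacy: str


def to_intensity(image: np.ndarray) -> np.ndarray:
    """Collapse an 8-bit image to one grayscale channel.

    Grayscale input is returned unchanged. For RGB, if all three channels are
    identical the common channel is returned; otherwise a Rec.-luma weighted
    average is rounded half-up to integers in [0, 255]. IR exports are often
    RGB files carrying a grayscale signal, so the fast path is the common one.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise FormatError(f"expected 8-bit image, got dtype {arr.dtype}")
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"unsupported channel layout {arr.shape}")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    if np.array_equal(r, g) and np.array_equal(g, b):
        return r.copy()
    wr, wg, wb = LUMA_WEIGHTS
    luma = wr * r.astype(float) + wg * g.astype(float) + wb * b.astype(float)
    return np.floor(luma + 0.5).astype(np.uint8)  # round half-up


def _as_mask(roi, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(roi, shapely.Polygon):
        roi = np.asarray(roi.exterior.coords[:-1], dtype=float)
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if roi.shape != tuple(shape):
            raise EmptyRoiError(
                f"mask shape {roi.shape} does not match image shape {tuple(shape)}"
            )
        return roi
    return rasterize_polygon(roi, shape)


def measure_mfi(intensity: np.ndarray, roi) -> MFIStats:
    """MFI statistics of a grayscale raster over an ROI (polygon or mask).

    ``sd`` is the population standard deviation over exactly the rasterized
    ROI pixels.
    """
    intensity = np.asarray(intensity)
    if intensity.ndim != 2:
        raise FormatError("measure_mfi expects a grayscale (h, w) raster")
    mask = _as_mask(roi, intensity.shape)
    values = intensity[mask].astype(float)
    if values.size == 0:
        raise EmptyRoiError("ROI contains no image pixels")
    return MFIStats(
        mean=float(values.mean()),
        minimum=float(values.min()),
        maximum=float(values.max()),
        sd=float(values.std(ddof=0)),
        n_pixels=int(values.size),
    )


def classify_ratio(value: float) -> str:
    """Adequacy class of a signal ratio: >=3 sufficient, [1.5, 3) suboptimal, <1.5 insufficient."""
    if value < 0:
        raise ValueError(f"signal ratio must be >= 0, got {value}")
    if value >= 3.0:
        return "sufficient"
    if value >= 1.5:
        return "suboptimal"
    return "insufficient"


def ratio(numerator: MFIStats, denominator: MFIStats, name: str = "TBR") -> RatioResult:
    """Ratio of ROI mean intensities with its adequacy class attached."""
    if denominator.mean == 0:
        raise UndefinedRatioError(
            "background ROI mean intensity is 0 (all-black reference region)"
        )
    value = numerator.mean / denominator.mean
    return RatioResult(name=name, value=value, adequacy=classify_ratio(value))


def ellipsoid_volume(d1: float, d2: float, d3: float) -> float:
    """Tumor volume (cm^3) from three linear diameters (cm): V = pi/6 * d1*d2*d3."""
    if min(d1, d2, d3) <= 0:
        raise ValueError("ellipsoid diameters must be positive")
    return math.pi / 6.0 * d1 * d2 * d3
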