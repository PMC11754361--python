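"""Histomorphometry of chromogenic (DAB) target staining.

Quantifies integrin staining the way automated histomorphometry platforms
do: separate the brown chromogen from the counterstain by color
deconvolution, threshold the chromogen optical density into a stained-pixel
mask, and report per-ROI the stained fraction, the stained area normalized
to 10 high-power fields (10 HPF = 2.37 mm²), and the mean staining
intensity (MI) of stained pixels.

MI is recorded on the raw pixel scale where stronger (darker) staining
gives LOWER values, so a specimen with more target expression has a higher
stained area but a lower MI — which is why MI correlates negatively with
fluorescence signal ratios while stained area correlates positively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from fgsquant.exceptions import ConfigError, EmptyRoiError, FormatError

#: Reference area of 10 high-power fields, in µm².
TEN_HPF_UM2 = 2.37e6

#: Default chromogen optical-density threshold for calling a pixel stained.
DEFAULT_STAIN_THRESHOLD = 0.15

#: Stained-fraction bins for the semiquantitative expression category.
#: Explicitly configuration, not a validated grading rubric: (positivity is
#: the >10% rule; the category boundaries are adjustable placeholders).
DEFAULT_CATEGORY_BINS = (0.10, 0.25, 0.50)

POSITIVITY_FRACTION = 0.10

#: Optical density treated as full-scale when mapping the chromogen channel
#: onto the 8-bit intensity scale.
_OD_FULL_SCALE = 1.0


@dataclass(frozen=True)
class IHCQuant:
    """Per-ROI staining quantification.

    ``stained_area`` is µm² per 10 HPF: ``stained_fraction * 2.37e6``.
    ``mean_intensity`` is the mean recorded pixel value over stained pixels
    (lower = darker = stronger staining); ``None`` when no pixel is stained.
    """

    roi_name: str
    stained_fraction: float
    stained_area: float
    mean_intensity: float | None
    um_per_pixel: float
    n_roi_pixels: int
    n_stained_pixels: int


@dataclass(frozen=True)
class ExpressionCall:
    positive: bool
    category: str  # none | low | intermediate | high
    category_bins: tuple[float, float, float]


def segment_stain(image: np.ndarray,
                  stain_threshold: float = DEFAULT_STAIN_THRESHOLD
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Separate the DAB chromogen and threshold it into a stained mask.

    Returns ``(stained_mask, intensity_raster)``. The chromogen channel is
    obtained by hematoxylin-eosin-DAB color deconvolution; the intensity
    raster is ``255 - scaled chromogen density`` so darker stain maps to
    lower recorded values.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError("segment_stain expects an RGB raster")
    if arr.dtype != np.uint8:
        raise FormatError(f"expected 8-bit RGB, got dtype {arr.dtype}")
    dab = skcolor.rgb2hed(arr)[..., 2]
    stained = dab > stain_threshold
    scaled = np.clip(dab / _OD_FULL_SCALE, 0.0, 1.0) * 255.0
    intensity = np.floor(255.0 - scaled + 0.5).astype(np.uint8)
    return stained, intensity


def quantify_roi(stained_mask: np.ndarray, intensity: np.ndarray, roi: np.ndarray,
                 um_per_pixel: float = 0.5, roi_name: str = "roi") -> IHCQuant:
    """Stained fraction, 10-HPF-normalized stained area and MI over one ROI."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise EmptyRoiError(f"ROI {roi_name!r} is empty")
    if roi.shape != stained_mask.shape or roi.shape != intensity.shape:
        raise FormatError("stained mask, intensity raster and ROI shapes must match")
    n_roi = int(roi.sum())
    in_roi = np.asarray(stained_mask, dtype=bool) & roi
    n_stained = int(in_roi.sum())
    fraction = n_stained / n_roi
    mean_intensity = float(intensity[in_roi].mean()) if n_stained else None
    return IHCQuant(
        roi_name=roi_name, stained_fraction=fraction,
        stained_area=fraction * TEN_HPF_UM2, mean_intensity=mean_intensity,
        um_per_pixel=um_per_pixel, n_roi_pixels=n_roi, n_stained_pixels=n_stained,
    )


def expression_call(quant_tumor: IHCQuant,
                    bins: tuple[float, float, float] = DEFAULT_CATEGORY_BINS
                    ) -> ExpressionCall:
    """Positivity (>10% stained) and the binned expression category."""
    bins = tuple(float(b) for b in bins)
    if len(bins) != 3 or not (0 < bins[0] < bins[1] < bins[2] <= 1):
        raise ConfigError(f"category bins must be strictly increasing in (0, 1]: {bins}")
    f = quant_tumor.stained_fraction
    if f <= bins[0]:
        category = "none"
    elif f <= bins[1]:
        category = "low"
    elif f <= bins[2]:
        category = "intermediate"
    else:
        category = "high"
    return ExpressionCall(positive=f > POSITIVITY_FRACTION, category=category,
                          category_bins=bins)
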