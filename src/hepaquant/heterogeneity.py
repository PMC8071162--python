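"""Liver heterogeneity (L_Het) scoring.

L_Het for one circular parenchymal ROI is the coefficient of variation
of its pixel intensities in percent, ``SD / mean * 100``; the subject's
L_Het score is the arithmetic mean over the placed ROIs (five by
default, at least three). A per-pixel L_Het map generalises the same
statistic to a sliding window restricted to the liver mask. Higher
scores indicate more heterogeneous parenchyma.

The SD is the sample standard deviation (divisor ``n - 1``) by default:
ROIs are small (~40 px) and the population-SD bias would not be
negligible. Pass ``ddof=0`` for the population flavour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError, PlacementError
from .image import BinaryMask, Image2D
from .phantom import CircularROI

MIN_ROI_PIXELS = 10
MIN_ROIS = 3


@dataclass
class HetResult:
    roi_cvs: list[float]  # per-ROI CV * 100
    lhet_score: float  # mean of roi_cvs
    n_rois: int


def roi_cv(image: Image2D, mask: BinaryMask, roi: CircularROI, ddof: int = 1) -> float:
    """CV * 100 of the image over one circular ROI.

    The ROI must lie entirely inside the liver mask (vessel/lesion
    pixels are masked out upstream, so an ROI that leaves the mask is a
    placement mistake, not a smaller sample).
    """
    mask.require_congruent(image)
    pix = roi.pixel_mask(image.shape)
    n = int(pix.sum())
    if n < MIN_ROI_PIXELS:
        raise PlacementError(f"ROI covers {n} px < {MIN_ROI_PIXELS}")
    if not np.all(mask.grid[pix]):
        raise PlacementError("ROI extends outside the liver mask")
    values = image.pixels[pix]
    mean = float(values.mean())
    if mean <= 0:
        raise DomainError("ROI mean must be positive for CV")
    sd = float(values.std(ddof=ddof))
    return sd / mean * 100.0


def lhet_score(
    image: Image2D, mask: BinaryMask, rois: list[CircularROI], ddof: int = 1
) -> HetResult:
    """Subject-level L_Het: mean CV*100 over at least three ROIs."""
    if len(rois) < MIN_ROIS:
        raise ConfigurationError(f"need at least {MIN_ROIS} ROIs, got {len(rois)}")
    cvs = [roi_cv(image, mask, roi, ddof=ddof) for roi in rois]
    return HetResult(roi_cvs=cvs, lhet_score=float(np.mean(cvs)), n_rois=len(cvs))


def lhet_map(
    image: Image2D, mask: BinaryMask, window_px: int = 7, ddof: int = 1
) -> np.ndarray:
    """Per-pixel sliding-window CV map (CV * 100) inside the mask.

    For each in-mask pixel the statistic is computed over the in-mask
    pixels of the centred ``window_px`` x ``window_px`` square. Pixels
    outside the mask, or whose window holds fewer than two in-mask
    pixels or a zero mean, are NaN.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ConfigurationError(f"window must be odd and >= 3, got {window_px}")
    mask.require_congruent(image)
    m = mask.grid.astype(np.float64)
    # centre intensities before the moments: the variance is shift-invariant
    # and this avoids catastrophic cancellation in s2 - s1^2/n
    shift = float(image.pixels[mask.grid].mean()) if mask.grid.any() else 0.0
    img_m = (image.pixels - shift) * m
    size = window_px
    # windowed sums via uniform filter (zero-padded borders)
    n = ndimage.uniform_filter(m, size=size, mode="constant") * size**2
    s1 = ndimage.uniform_filter(img_m, size=size, mode="constant") * size**2
    s2 = ndimage.uniform_filter(img_m**2, size=size, mode="constant") * size**2

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n + shift
        var = (s2 - s1**2 / n) / np.maximum(n - ddof, 1e-12)
        np.clip(var, 0.0, None, out=var)  # guard tiny negative round-off
        cv = np.sqrt(var) / mean * 100.0
    out = np.full(image.shape, np.nan)
    valid = mask.grid & (n >= 2) & (mean > 0)
    out[valid] = cv[valid]
    return out
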