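"""Liver surface nodularity (L_Nod) scoring.

Each user-selected surface segment is compared against a smooth
low-order polynomial reference curve fitted to it: both coordinates are
regressed on normalised arc length by ordinary least squares, and the
point-wise (index-aligned) Euclidean deviations between the surface
line and the fitted line, in millimetres, are pooled into a root mean
square. The subject's L_Nod score is the mean RMS over the segments
(at least three). Higher scores indicate a more nodular surface.

The per-segment score is an RMS rather than a mean or variance of the
squared deviations so that it carries distance units (mm) and scales
linearly with the nodularity amplitude; for a sinusoidal perturbation
of amplitude A riding on a curve the fit can follow, the score
converges to A / sqrt(2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .contour import SurfaceSegment
from .errors import AlignmentError, ConfigurationError, RangeError

ALLOWED_ORDERS = (2, 3, 4)
MIN_SEGMENTS = 3
DEFAULT_ORDER = 3


@dataclass
class PolyFit:
    """Polynomial reference curve for one surface segment."""

    order: int
    coeffs_row: np.ndarray  # power-basis coefficients over normalised arc length
    coeffs_col: np.ndarray
    fitted_points: np.ndarray  # (n, 2), index-aligned with the segment
    rank_deficient: bool = False


@dataclass
class NodResult:
    roi_rms_mm: list[float]
    lnod_score: float
    order: int


def fit_segment(segment: SurfaceSegment, order: int = DEFAULT_ORDER) -> PolyFit:
    """Least-squares polynomial reference line over normalised arc length.

    Row and column coordinates are fitted independently; the fitted
    point for index ``i`` is the polynomial evaluated at the segment's
    own arc-length parameter ``i``. A rank-deficient design (degenerate
    segment geometry) is flagged but the fit proceeds.
    """
    if order not in ALLOWED_ORDERS:
        raise ConfigurationError(f"order must be one of {ALLOWED_ORDERS}, got {order}")
    n = len(segment)
    if n < order + 2:
        raise RangeError(f"segment has {n} points; need >= {order + 2} for order {order}")
    t = segment.arclength_mm / segment.arclength_mm[-1]  # normalised to [0, 1]
    rank_deficient = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        prow = Polynomial.fit(t, segment.points[:, 0], deg=order)
        pcol = Polynomial.fit(t, segment.points[:, 1], deg=order)
        rank_deficient = any("conditioned" in str(w.message).lower() for w in caught)
    fitted = np.column_stack([prow(t), pcol(t)])
    return PolyFit(
        order=order,
        coeffs_row=prow.convert().coef,
        coeffs_col=pcol.convert().coef,
        fitted_points=fitted,
        rank_deficient=rank_deficient,
    )


def segment_nodularity(
    segment: SurfaceSegment, fit: PolyFit, spacing_mm: tuple[float, float] | None = None
) -> float:
    """RMS point-wise deviation (mm) between segment and its fitted line."""
    if len(fit.fitted_points) != len(segment):
        raise AlignmentError(
            f"fit has {len(fit.fitted_points)} points, segment {len(segment)}"
        )
    sr, sc = spacing_mm if spacing_mm is not None else segment.spacing_mm
    d = segment.points - fit.fitted_points
    dist_mm = np.hypot(d[:, 0] * sr, d[:, 1] * sc)
    return float(np.sqrt(np.mean(dist_mm**2)))


def lnod_score(
    segments: list[SurfaceSegment],
    order: int = DEFAULT_ORDER,
    spacing_mm: tuple[float, float] | None = None,
) -> NodResult:
    """Subject-level L_Nod: mean per-segment RMS over at least three segments."""
    if len(segments) < MIN_SEGMENTS:
        raise ConfigurationError(f"need at least {MIN_SEGMENTS} segments, got {len(segments)}")
    rms = [
        segment_nodularity(seg, fit_segment(seg, order=order), spacing_mm=spacing_mm)
        for seg in segments
    ]
    return NodResult(roi_rms_mm=rms, lnod_score=float(np.mean(rms)), order=order)
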