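"""Liver reference-line extraction and surface-segment selection.

The segmented liver boundary ("reference line") is traced at sub-pixel
resolution with marching squares, lightly smoothed to suppress the
half-pixel quantisation ripple of a binary mask, and cut into open
arc-length-parameterised segments for nodularity scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DegenerateInputError, RangeError
from .image import BinaryMask

MIN_COMPONENT_PX = 64
MIN_CLOSED_POINTS = 8
MIN_SEGMENT_MM = 20.0


def _signed_area(points: np.ndarray) -> float:
    """Shoelace area with x = col, y = row; positive is the package's CCW."""
    y = points[:, 0]
    x = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """Ordered sub-pixel boundary polyline in ``(row, col)`` coordinates.

    Closed contours have at least 8 vertices, no consecutive duplicates
    and counter-clockwise orientation (positive shoelace area in
    row/col axes). The last point does not repeat the first.
    """

    points: np.ndarray
    closed: bool = True
    spacing_mm: tuple[float, float] = (0.74, 0.74)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DegenerateInputError(f"contour points must be (n, 2), got {pts.shape}")
        # drop consecutive duplicates (including a repeated closing vertex)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
        pts = pts[keep]
        if self.closed and len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if self.closed:
            if len(pts) < MIN_CLOSED_POINTS:
                raise DegenerateInputError(
                    f"closed contour needs >= {MIN_CLOSED_POINTS} points, got {len(pts)}"
                )
            if _signed_area(pts) < 0:
                pts = pts[::-1].copy()
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def perimeter_px(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))

    def perimeter_mm(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        d = np.diff(pts, axis=0)
        sr, sc = self.spacing_mm
        return float(np.sum(np.hypot(d[:, 0] * sr, d[:, 1] * sc)))


@dataclass
class SurfaceSegment:
    """Open sub-list of a contour with cumulative arc length in mm."""

    points: np.ndarray
    spacing_mm: tuple[float, float] = (0.74, 0.74)
    arclength_mm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise RangeError(f"segment needs >= 2 (n, 2) points, got shape {pts.shape}")
        d = np.diff(pts, axis=0)
        sr, sc = self.spacing_mm
        step = np.hypot(d[:, 0] * sr, d[:, 1] * sc)
        if np.any(step <= 0):
            raise RangeError("segment has consecutive duplicate points")
        self.points = pts
        self.arclength_mm = np.concatenate([[0.0], np.cumsum(step)])

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length_mm(self) -> float:
        return float(self.arclength_mm[-1])


def _periodic_gaussian_smooth(points: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return points
    return np.column_stack(
        [ndimage.gaussian_filter1d(points[:, j], sigma, mode="wrap") for j in (0, 1)]
    )


def extract_contour(
    mask: BinaryMask,
    spacing_mm: tuple[float, float] = (0.74, 0.74),
    smooth_sigma: float = 2.0,
) -> Contour:
    """Trace the closed boundary of the mask's largest connected component.

    Marching squares at level 0.5 gives a sub-pixel polygon; a periodic
    Gaussian smoothing of the vertex coordinates (``smooth_sigma`` in
    vertex units, default 2) removes the half-pixel staircase ripple that
    rasterisation imprints on the curve while leaving features longer
    than ~10 vertices essentially intact. Interior holes are ignored.

    Raises
    ------
    DegenerateInputError
        Empty mask, dominant component below 64 px, or a component that
        touches the image border (its marching-squares contour is open).
    """
    grid = mask.grid
    labels, n = ndimage.label(grid)
    if n == 0:
        raise DegenerateInputError("mask is empty")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < MIN_COMPONENT_PX:
        raise DegenerateInputError(
            f"dominant component has {int(sizes[biggest - 1])} px < {MIN_COMPONENT_PX}"
        )
    component = ndimage.binary_fill_holes(labels == biggest)
    contours = measure.find_contours(component.astype(float), 0.5)
    if not contours:
        raise DegenerateInputError("no level-0.5 contour found")
    poly = max(contours, key=len)
    if not np.allclose(poly[0], poly[-1]):
        raise DegenerateInputError("component touches the image border; contour is open")
    poly = poly[:-1]  # drop repeated closing vertex before smoothing
    poly = _periodic_gaussian_smooth(poly, smooth_sigma)
    return Contour(points=poly, closed=True, spacing_mm=spacing_mm)


def select_segment(contour: Contour, start_index: int, end_index: int) -> SurfaceSegment:
    """Cut an open surface segment out of a closed contour.

    The segment runs forward (in contour order) from ``start_index`` to
    ``end_index``; when ``start_index > end_index`` it wraps through the
    contour's end. Cumulative arc length is in millimetres and must reach
    at least 20 mm.
    """
    n = len(contour)
    if not (0 <= start_index < n and 0 <= end_index < n):
        raise RangeError(f"indices ({start_index}, {end_index}) outside [0, {n})")
    if start_index == end_index:
        raise RangeError("start and end index coincide: empty segment")
    if start_index < end_index:
        pts = contour.points[start_index : end_index + 1]
    else:  # wrap-around
        pts = np.vstack([contour.points[start_index:], contour.points[: end_index + 1]])
    segment = SurfaceSegment(points=pts, spacing_mm=contour.spacing_mm)
    if segment.length_mm < MIN_SEGMENT_MM:
        raise RangeError(
            f"segment arc length {segment.length_mm:.2f} mm < {MIN_SEGMENT_MM} mm"
        )
    return segment
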