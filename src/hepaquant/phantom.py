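"""Synthetic axial liver-slice phantom with analytic ground truth.

The phantom emulates a T1-weighted axial slice at 0.74 mm in-plane
spacing: an elliptical "liver" whose boundary radius is perturbed by a
sinusoid (the nodularity), filled with Gaussian-noise parenchyma of
known coefficient of variation, modulated by a smooth multiplicative
bias field, on a darker uniform background. Every generated feature has
a closed-form truth value, so downstream scores can be validated by
parameter recovery:

* true interior CV is the requested ``parenchyma_cv``;
* the RMS radial deviation of the boundary from the smooth ellipse is
  ``nodularity_amplitude_mm / sqrt(2)`` (RMS of a sinusoid);
* the bias field has mean exactly 1 over the liver mask and range
  ``[1 - bias_amplitude, 1 + bias_amplitude]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .contour import Contour
from .errors import PlacementError, SpecError
from .image import BinaryMask, Image2D

_MARGIN_PX = 5
_N_BIAS_BUMPS = 4
_BOUNDARY_SAMPLES = 720


@dataclass
class PhantomSpec:
    """Parameters of one synthetic liver slice. Lengths are in mm."""

    shape: tuple[int, int] = (256, 256)
    spacing_mm: tuple[float, float] = (0.74, 0.74)
    liver_center: Optional[tuple[float, float]] = None  # (row, col) px; image centre if None
    liver_radii_mm: tuple[float, float] = (70.0, 52.0)  # (col/x, row/y) semi-axes
    nodularity_amplitude_mm: float = 0.0
    nodularity_frequency: int = 12  # sinusoid lobes per circumference
    parenchyma_mean: float = 100.0
    parenchyma_cv: float = 0.05
    bias_amplitude: float = 0.0
    bias_scale_mm: float = 40.0
    background_mean: float = 20.0
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.liver_center is None:
            self.liver_center = ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)
        if self.parenchyma_mean <= 0:
            raise SpecError("parenchyma_mean must be positive")
        if not (0 <= self.parenchyma_cv < 0.5):
            raise SpecError("parenchyma_cv must lie in [0, 0.5)")
        if not (0 <= self.bias_amplitude < 1):
            raise SpecError("bias_amplitude must lie in [0, 1)")
        if self.nodularity_amplitude_mm < 0:
            raise SpecError("nodularity_amplitude_mm must be >= 0")
        if self.nodularity_frequency < 1:
            raise SpecError("nodularity_frequency must be >= 1")
        if min(self.liver_radii_mm) <= 0 or self.bias_scale_mm <= 0:
            raise SpecError("length scales must be positive")
        # the perturbed ellipse must fit with a 5-px margin on every side
        r0, c0 = self.liver_center
        sr, sc = self.spacing_mm
        max_r_mm = max(self.liver_radii_mm) + self.nodularity_amplitude_mm
        if (
            r0 - max_r_mm / sr < _MARGIN_PX
            or r0 + max_r_mm / sr > self.shape[0] - 1 - _MARGIN_PX
            or c0 - max_r_mm / sc < _MARGIN_PX
            or c0 + max_r_mm / sc > self.shape[1] - 1 - _MARGIN_PX
        ):
            raise SpecError("liver ellipse (plus nodularity) exceeds image bounds/margin")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom slice."""

    mask: BinaryMask
    bias: np.ndarray
    smooth_boundary: Contour
    true_cv: float
    true_nodularity_rms_mm: float
    spec: PhantomSpec = field(repr=False, default=None)


@dataclass
class CircularROI:
    """Circular region of interest; pixels are those whose centres fall
    within ``radius_px`` of ``center``."""

    center: tuple[float, float]
    radius_px: float
    target_area_px: int

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius_px**2


def _ellipse_radius_mm(theta: np.ndarray, a_mm: float, b_mm: float) -> np.ndarray:
    # polar radius of an axis-aligned ellipse, a along x (cols), b along y (rows)
    return a_mm * b_mm / np.sqrt((b_mm * np.cos(theta)) ** 2 + (a_mm * np.sin(theta)) ** 2)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive field: Gaussian-bump mixture, centred to mean 1 over
    the liver mask and scaled to peak deviation ``bias_amplitude``."""
    rows, cols = spec.shape
    sr, sc = spec.spacing_mm
    y = np.arange(rows)[:, None] * sr
    x = np.arange(cols)[None, :] * sc
    f = np.zeros(spec.shape)
    for _ in range(_N_BIAS_BUMPS):
        cy = rng.uniform(0, (rows - 1) * sr)
        cx = rng.uniform(0, (cols - 1) * sc)
        w = rng.uniform(-1.0, 1.0)
        f += w * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * spec.bias_scale_mm**2))
    return f


def generate_phantom(spec: PhantomSpec) -> tuple[Image2D, PhantomTruth]:
    """Render the phantom slice and its ground truth.

    Deterministic for a given ``spec`` (all randomness flows from
    ``spec.noise_seed``). Interior intensity is
    ``mean * bias * (1 + cv * g)`` with ``g`` standard normal; the
    background uses the same relative noise around ``background_mean``
    (without bias), keeping the slice two-phase.
    """
    rng = np.random.default_rng(spec.noise_seed)
    rows, cols = spec.shape
    sr, sc = spec.spacing_mm
    r0, c0 = spec.liver_center
    a_mm, b_mm = spec.liver_radii_mm

    rr, cc = np.mgrid[0:rows, 0:cols]
    dy = (rr - r0) * sr
    dx = (cc - c0) * sc
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dx, dy)
    r_boundary = _ellipse_radius_mm(theta, a_mm, b_mm) + spec.nodularity_amplitude_mm * np.sin(
        spec.nodularity_frequency * theta
    )
    mask = rho <= r_boundary

    # bias: mean exactly 1 over the mask, extreme deviation = bias_amplitude
    if spec.bias_amplitude > 0:
        f = _bias_field(spec, rng)
        f = f - f[mask].mean()
        peak = np.max(np.abs(f))
        bias = 1.0 + (spec.bias_amplitude / peak) * f if peak > 0 else np.ones(spec.shape)
    else:
        bias = np.ones(spec.shape)

    g = rng.standard_normal(spec.shape)
    interior = spec.parenchyma_mean * bias * (1.0 + spec.parenchyma_cv * g)
    background = spec.background_mean * (1.0 + spec.parenchyma_cv * g)
    pixels = np.where(mask, interior, background)
    np.clip(pixels, 0.0, None, out=pixels)

    t = np.linspace(0, 2 * np.pi, _BOUNDARY_SAMPLES, endpoint=False)
    r_ell = _ellipse_radius_mm(t, a_mm, b_mm)
    boundary_pts = np.column_stack([r0 + r_ell * np.sin(t) / sr, c0 + r_ell * np.cos(t) / sc])
    truth = PhantomTruth(
        mask=BinaryMask(mask),
        bias=bias,
        smooth_boundary=Contour(points=boundary_pts, closed=True, spacing_mm=spec.spacing_mm),
        true_cv=spec.parenchyma_cv,
        true_nodularity_rms_mm=spec.nodularity_amplitude_mm / np.sqrt(2.0),
        spec=spec,
    )
    image = Image2D(
        pixels=pixels,
        spacing_mm=spec.spacing_mm,
        meta={"source": "phantom", "noise_seed": spec.noise_seed},
    )
    return image, truth


def sample_circular_rois(
    truth: PhantomTruth,
    n: int = 5,
    area_px: int = 40,
    seed: int = 0,
    min_boundary_px: float = 2.0,
    max_tries: int = 2000,
) -> list[CircularROI]:
    """Draw ``n`` disjoint circular ROIs inside the liver mask.

    Emulates manual parenchymal ROI placement: every ROI lies fully
    inside the mask, at least ``min_boundary_px`` from its boundary
    (avoiding the subcapsular rim), and ROIs are pairwise disjoint.
    Placement is rejection sampling behind a single seed.
    """
    from scipy import ndimage  # local import keeps module import light

    if n < 1:
        raise PlacementError("need at least one ROI")
    radius = float(np.sqrt(area_px / np.pi))
    dist = ndimage.distance_transform_edt(truth.mask.grid)
    valid = np.argwhere(dist >= radius + min_boundary_px)
    if len(valid) == 0:
        raise PlacementError(f"mask cannot host an ROI of area {area_px} px")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    for _ in range(max_tries):
        r, c = valid[rng.integers(len(valid))]
        if all(np.hypot(r - rc, c - cc) > 2 * radius + 1e-9 for rc, cc in centers):
            centers.append((float(r), float(c)))
            if len(centers) == n:
                break
    if len(centers) < n:
        raise PlacementError(
            f"could not place {n} disjoint ROIs of area {area_px} px in {max_tries} tries"
        )
    return [CircularROI(center=c, radius_px=radius, target_area_px=area_px) for c in centers]
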