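"""Core in-memory containers: 2-D grayscale slice and congruent binary mask.

Coordinates are 0-based ``(row, col)`` throughout the package; physical
positions are pixel indices scaled by the per-axis spacing in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import DomainError

MIN_SIDE = 32  # smallest usable slice side, in pixels


@dataclass
class Image2D:
    """A single grayscale slice with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (arbitrary units;
        MR magnitude images are non-negative by construction).
    spacing_mm
        ``(row, col)`` pixel spacing in millimetres, both positive.
    meta
        Free-form metadata (patient pseudo-ID, slice description, ...).
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float] = (0.74, 0.74)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DomainError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < MIN_SIDE:
            raise DomainError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise DomainError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise DomainError("pixels must be non-negative")
        sr, sc = self.spacing_mm
        if not (sr > 0 and sc > 0):
            raise DomainError(f"spacings must be positive, got {self.spacing_mm}")
        self.spacing_mm = (float(sr), float(sc))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean grid congruent with an :class:`Image2D`."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise DomainError(f"mask must be 2-D, got shape {self.grid.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    def require_congruent(self, image: Image2D) -> None:
        if self.grid.shape != image.pixels.shape:
            raise DomainError(
                f"mask shape {self.grid.shape} does not match image {image.pixels.shape}"
            )
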