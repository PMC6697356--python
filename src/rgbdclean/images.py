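"""Pixel-grid containers: depth images, color images and the mapping image.

The *mapping image* is the color image resampled onto the depth sensor's
pixel grid, so that every depth pixel carries an RGB value. It is the
intermediate the whole segmentation pipeline operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ShapeError

__all__ = ["DepthImage", "ColorImage", "MappingImage"]


@dataclass
class DepthImage:
    """Organized depth grid in meters; 0 marks an invalid (missing) sample.

    ``depth_scale`` records the meters-per-stored-unit factor used when the
    image is round-tripped through 16-bit PNG (RealSense convention:
    0.001 m per unit, i.e. millimeters on disk).
    """

    values: np.ndarray
    depth_scale: float = 0.001

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ShapeError(f"depth image must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise DomainError("depth values must be finite")
        if np.any(v < 0):
            raise DomainError("depth values must be >= 0")
        if self.depth_scale <= 0:
            raise DomainError(f"depth_scale must be positive, got {self.depth_scale}")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean grid: True where a depth sample exists."""
        return self.values > 0


@dataclass
class ColorImage:
    """H x W x 3 RGB grid, either 8-bit integers [0, 255] or reals [0, 1].

    The ``normalized`` flag records which convention ``values`` uses; the
    segmentation stage requires the normalized form.
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.shape[2] != 3:
            raise ShapeError(f"color image must be H x W x 3, got shape {v.shape}")
        if self.normalized:
            v = np.asarray(v, dtype=float)
            if v.size and (v.min() < 0 or v.max() > 1):
                raise DomainError("normalized color values must lie in [0, 1]")
        else:
            if v.size and (v.min() < 0 or v.max() > 255):
                raise DomainError("8-bit color values must lie in [0, 255]")
            v = v.astype(np.uint8)
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


@dataclass
class MappingImage:
    """Color resampled onto the depth grid, with per-pixel validity.

    ``valid`` is False where the depth was missing or the pixel projected
    outside the color image; those pixels hold color (0, 0, 0).
    """

    color: ColorImage
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.color.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.color.shape:
            raise ShapeError(
                f"validity shape {self.valid.shape} != color shape {self.color.shape}"
            )
        if np.any(self.color.values[~self.valid] != 0):
            raise DomainError("invalid mapping pixels must hold color (0, 0, 0)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.color.shape

    @property
    def values(self) -> np.ndarray:
        return self.color.values
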