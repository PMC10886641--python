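"""Calibrated image containers shared across the pipeline.

A :class:`Micrograph` is a single-plane grayscale fluorescence image with a
pixel-size calibration (pixels per micron) and a nominal camera bit depth.
A :class:`BinaryMask` is the segmentation result and inherits the
calibration so that downstream morphometrics can report lengths in µm and
areas in µm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Default calibration of the confocal acquisitions this pipeline targets.
DEFAULT_PIXELS_PER_MICRON = 23.4


@dataclass
class Micrograph:
    """Single-plane grayscale fluorescence image with calibration.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Non-negative intensities, stored as float64.
    bit_depth : {8, 16}
        Nominal camera bit depth; sets the intensity range used by
        histogram-based operators (CLAHE, Otsu).
    pixels_per_micron : float
        Lateral calibration in pixels per micron.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixels_per_micron > 0:
            raise ValueError("pixels_per_micron must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def intensity_max(self) -> int:
        """Full-scale value for the nominal bit depth."""
        return (1 << self.bit_depth) - 1

    def with_pixels(self, pixels: np.ndarray) -> "Micrograph":
        """Return a copy carrying the same calibration but new pixel data."""
        return Micrograph(pixels, self.bit_depth, self.pixels_per_micron)

    def to_tiff(self, path: str | Path) -> None:
        """Write as single-plane grayscale TIFF, quantized to bit depth."""
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        data = np.clip(np.rint(self.pixels), 0, self.intensity_max).astype(dtype)
        tifffile.imwrite(str(path), data)

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON,
    ) -> "Micrograph":
        """Read a single-plane grayscale TIFF."""
        data = tifffile.imread(str(path))
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-plane grayscale TIFF")
        bit_depth = 8 if data.dtype == np.uint8 else 16
        return cls(data.astype(np.float64), bit_depth, pixels_per_micron)


@dataclass
class BinaryMask:
    """Boolean foreground mask inheriting the source calibration."""

    pixels: np.ndarray
    pixels_per_micron: float = DEFAULT_PIXELS_PER_MICRON

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {self.pixels.shape}")
        if not self.pixels_per_micron > 0:
            raise ValueError("pixels_per_micron must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_fraction(self) -> float:
        return float(self.pixels.mean())
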