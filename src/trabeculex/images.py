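"""Core image containers.

All processing operates on plain 2-D numpy arrays wrapped with the physical
pixel size so that lengths and areas can be reported in mm / cm**2.  Gray
values live on the 8-bit scale [0, 255] but are stored as float64 between
stages to avoid accumulating rounding error; PNG round-trips quantize to
uint8.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = ["GrayImage", "BinaryImage", "SkeletonImage", "read_gray", "write_gray", "write_mask"]


def _check_grid(a: np.ndarray, name: str) -> None:
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {a.shape}")


@dataclass
class GrayImage:
    """8-bit-scale grayscale image with physical pixel size.

    Row index increases downward; (0, 0) is the top-left pixel.
    """

    pixels: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        _check_grid(self.pixels, "pixels")
        if self.pixel_size_mm <= 0:
            raise ValueError(f"pixel_size_mm must be positive, got {self.pixel_size_mm}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryImage:
    """Boolean foreground mask (True = high-density / bone)."""

    mask: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_grid(self.mask, "mask")
        if self.pixel_size_mm <= 0:
            raise ValueError(f"pixel_size_mm must be positive, got {self.pixel_size_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SkeletonImage:
    """One-pixel-wide curve network produced by topology-preserving thinning."""

    mask: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_grid(self.mask, "mask")
        if self.pixel_size_mm <= 0:
            raise ValueError(f"pixel_size_mm must be positive, got {self.pixel_size_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def read_gray(path, pixel_size_mm: float) -> GrayImage:
    """Read an 8-bit grayscale PNG/TIFF into a :class:`GrayImage`."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) written by external tools
        arr = arr[..., :3].mean(axis=2)
    return GrayImage(np.asarray(arr, dtype=np.float64), pixel_size_mm)


def write_gray(path, image: GrayImage) -> None:
    iio.imwrite(path, np.clip(np.round(image.pixels), 0, 255).astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
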