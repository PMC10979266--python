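"""Radiograph preprocessing chain: crop, upsample, blur, density-correct,
binarize, skeletonize.

The chain implements the White–Rudolph trabecular segmentation approach:
the ROI is enlarged 4x by bicubic interpolation, heavily blurred (sigma 35
with a 33-tap truncated kernel — effectively a local mean), the blurred copy
is subtracted from the original and offset by 128 to remove large-scale
density variation, and the result is cut at 128 so that pixels above their
local mean become foreground (bone).  The binary mask is then thinned to a
one-pixel-wide skeleton for strut and fractal analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import thin as _guo_hall_thin
from skimage.transform import resize as _sk_resize

from .images import BinaryImage, GrayImage, SkeletonImage

__all__ = [
    "RoiSpec",
    "ChainConfig",
    "ChainResult",
    "extract_roi",
    "upsample",
    "gaussian_blur",
    "density_correct",
    "binarize",
    "skeletonize",
    "run_chain",
]

ROI_LABELS = ("ROI1", "ROI2", "ROI3", "ROI4")


@dataclass(frozen=True)
class RoiSpec:
    """Square region of interest: anatomical label, center pixel, side in mm.

    ROI1–ROI4 are the condylar head, ramus, inter-molar region and endosteal
    margin; their anatomical placement is manual, so only the geometry is
    handled here.
    """

    label: str
    center_row: int
    center_col: int
    side_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        if self.side_mm <= 0:
            raise ValueError("side_mm must be positive")


@dataclass(frozen=True)
class ChainConfig:
    """Parameters of the preprocessing chain (defaults follow the protocol)."""

    upsample_factor: int = 4
    sigma_px: float = 35.0
    kernel_px: int = 33
    threshold: float = 128.0


@dataclass
class ChainResult:
    """All intermediates of one chain run, kept for audit."""

    roi: GrayImage
    upsampled: GrayImage
    blurred: GrayImage
    corrected: GrayImage
    binary: BinaryImage
    skeleton: SkeletonImage


def _side_px(side_mm: float, pixel_size_mm: float) -> int:
    # round-half-up; the protocol states the ROI size only in mm
    return int(math.floor(side_mm / pixel_size_mm + 0.5))


def extract_roi(image: GrayImage, spec: RoiSpec) -> GrayImage:
    """Crop the square ROI; errors name the edge that would be exceeded."""
    side = _side_px(spec.side_mm, image.pixel_size_mm)
    r0 = spec.center_row - side // 2
    c0 = spec.center_col - side // 2
    h, w = image.shape
    if r0 < 0:
        raise ValueError(f"ROI {spec.label} exceeds the top edge (row {r0})")
    if c0 < 0:
        raise ValueError(f"ROI {spec.label} exceeds the left edge (col {c0})")
    if r0 + side > h:
        raise ValueError(f"ROI {spec.label} exceeds the bottom edge (row {r0 + side} > {h})")
    if c0 + side > w:
        raise ValueError(f"ROI {spec.label} exceeds the right edge (col {c0 + side} > {w})")
    return GrayImage(image.pixels[r0:r0 + side, c0:c0 + side].copy(), image.pixel_size_mm)


def upsample(image: GrayImage, factor: int = 4) -> GrayImage:
    """Bicubic enlargement by an integer factor; pixel size shrinks accordingly."""
    if int(factor) != factor or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return GrayImage(image.pixels.copy(), image.pixel_size_mm)
    h, w = image.shape
    out = _sk_resize(image.pixels, (h * factor, w * factor), order=3,
                     mode="edge", anti_aliasing=False)
    return GrayImage(np.clip(out, 0, 255), image.pixel_size_mm / factor)


def _gaussian_kernel(sigma_px: float, kernel_px: int) -> np.ndarray:
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError(f"kernel_px must be an odd positive integer, got {kernel_px}")
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    radius = (kernel_px - 1) // 2
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma_px**2))
    return k / k.sum()


def gaussian_blur(image: GrayImage, sigma_px: float = 35.0, kernel_px: int = 33) -> GrayImage:
    """Separable Gaussian blur with a truncated, renormalized kernel.

    With the default sigma 35 / 33 taps the kernel is nearly flat, so the
    blur acts as a ~33-pixel local mean; boundaries are handled by
    reflection.
    """
    k = _gaussian_kernel(sigma_px, kernel_px)
    out = ndi.correlate1d(image.pixels, k, axis=0, mode="reflect")
    out = ndi.correlate1d(out, k, axis=1, mode="reflect")
    return GrayImage(np.clip(out, 0, 255), image.pixel_size_mm)


def density_correct(original: GrayImage, blurred: GrayImage) -> GrayImage:
    """Per-pixel ``original - blurred + 128``, clamped to [0, 255].

    The result is snapped to 1e-6 gray levels so that exact ties (e.g. a
    flat image, whose residual is identically zero) sit exactly on the 128
    binarization threshold instead of a float epsilon below it.
    """
    if original.shape != blurred.shape:
        raise ValueError(f"shape mismatch: {original.shape} vs {blurred.shape}")
    out = np.clip(np.round(original.pixels - blurred.pixels + 128.0, 6), 0, 255)
    return GrayImage(out, original.pixel_size_mm)


def binarize(image: GrayImage, threshold: float = 128.0) -> BinaryImage:
    """Foreground where intensity >= threshold (high intensity = bone)."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    return BinaryImage(image.pixels >= threshold, image.pixel_size_mm)


def skeletonize(binary: BinaryImage) -> SkeletonImage:
    """Topology-preserving thinning (Guo–Hall) to one-pixel-wide curves."""
    return SkeletonImage(_guo_hall_thin(binary.mask), binary.pixel_size_mm)


def run_chain(image: GrayImage, spec: Optional[RoiSpec] = None,
              config: ChainConfig = ChainConfig()) -> ChainResult:
    """Apply the full chain in protocol order, returning every intermediate."""
    roi = extract_roi(image, spec) if spec is not None else image
    up = upsample(roi, config.upsample_factor)
    blurred = gaussian_blur(up, config.sigma_px, config.kernel_px)
    corrected = density_correct(up, blurred)
    binary = binarize(corrected, config.threshold)
    skeleton = skeletonize(binary)
    return ChainResult(roi=roi, upsampled=up, blurred=blurred, corrected=corrected,
                       binary=binary, skeleton=skeleton)
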