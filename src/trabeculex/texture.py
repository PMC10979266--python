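"""Texture descriptors: GLCM Haralick features and box-counting fractal dimension.

The grey-level co-occurrence matrix (GLCM) is the joint distribution of
quantized intensity pairs at a fixed pixel offset; contrast, correlation,
energy and homogeneity summarize it.  The fractal dimension of the
skeletonized trabecular network is estimated by box counting: the negative
slope of log(occupied boxes) against log(box size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .images import BinaryImage, GrayImage, SkeletonImage

__all__ = [
    "GlcmMatrix",
    "GlcmFeatures",
    "FractalResult",
    "compute_glcm",
    "glcm_features",
    "box_counting_fd",
    "default_box_sizes",
]

logger = logging.getLogger(__name__)


@dataclass
class GlcmMatrix:
    """Normalized co-occurrence probabilities at one offset."""

    probabilities: np.ndarray  # (levels, levels), sums to 1
    levels: int
    offset: tuple[int, int]
    symmetric: bool

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (self.levels, self.levels):
            raise ValueError("probabilities must be (levels, levels)")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.probabilities = p


@dataclass
class GlcmFeatures:
    """Haralick summaries; correlation is NaN when either marginal is constant."""

    contrast: float
    correlation: float
    energy: float
    homogeneity: float


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize 8-bit-scale intensities into ``levels`` bins."""
    q = np.floor(np.asarray(pixels, dtype=np.float64) * (levels / 256.0)).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    image: GrayImage,
    offset: tuple[int, int] = (0, 1),
    levels: int = 256,
    symmetric: bool = True,
) -> GlcmMatrix:
    """Accumulate co-occurrence counts over all in-bounds pixel pairs at ``offset``."""
    dr, dc = int(offset[0]), int(offset[1])
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    h, w = image.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset {offset} does not fit inside image of shape {(h, w)}")

    q = quantize(image.pixels, levels)
    # source and destination windows for the displacement (dr, dc)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if src.size == 0:
        raise ValueError("no valid pixel pairs at this offset")

    counts = np.bincount(
        (src.ravel() * levels + dst.ravel()), minlength=levels * levels
    ).reshape(levels, levels).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return GlcmMatrix(counts / counts.sum(), levels=levels, offset=(dr, dc),
                      symmetric=symmetric)


def glcm_features(glcm: GlcmMatrix) -> GlcmFeatures:
    """Contrast, correlation, energy and homogeneity of one GLCM.

    contrast  = sum (i-j)^2 p(i,j)
    energy    = sum p(i,j)^2
    homogen.  = sum p(i,j) / (1 + |i-j|)
    correl.   = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j), NaN if a
                marginal has zero variance (e.g. a constant image).
    Indices are quantized bin indices.
    """
    p = glcm.probabilities
    idx = np.arange(glcm.levels, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((idx * pi).sum())
    mu_j = float((idx * pj).sum())
    var_i = float(((idx - mu_i) ** 2 * pi).sum())
    var_j = float(((idx - mu_j) ** 2 * pj).sum())
    if var_i <= 1e-12 or var_j <= 1e-12:
        correlation = float("nan")
    else:
        correlation = float(((i - mu_i) * (j - mu_j) * p).sum() / np.sqrt(var_i * var_j))
    return GlcmFeatures(contrast=contrast, correlation=correlation, energy=energy,
                        homogeneity=homogeneity)


@dataclass
class FractalResult:
    """Box-counting estimate with the underlying counts and fit quality."""

    fd: float
    box_sizes: np.ndarray
    box_counts: np.ndarray
    r_squared: float


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Powers of 2 from 2 up to a quarter of the shorter image side."""
    limit = min(shape) // 4
    sizes = []
    s = 2
    while s <= limit:
        sizes.append(s)
        s *= 2
    return sizes


def _count_boxes(mask: np.ndarray, size: int) -> int:
    h, w = mask.shape
    ph = (-h) % size
    pw = (-w) % size
    padded = np.pad(mask, ((0, ph), (0, pw)))  # partial edge boxes included
    blocks = padded.reshape(padded.shape[0] // size, size, padded.shape[1] // size, size)
    return int(blocks.any(axis=(1, 3)).sum())


def box_counting_fd(
    skeleton: Union[SkeletonImage, BinaryImage, np.ndarray],
    box_sizes: Optional[Sequence[int]] = None,
) -> FractalResult:
    """Box-counting fractal dimension of a binary pattern.

    The image is tiled from the top-left with s x s boxes (partial boxes at
    the edges count) and the occupied-box count is regressed on box size in
    log-log coordinates; fd is the negative slope.  A poor fit
    (r^2 < 0.9) is logged as a warning, not raised.
    """
    mask = np.asarray(getattr(skeleton, "mask", skeleton), dtype=bool)
    if not mask.any():
        raise ValueError("cannot estimate a fractal dimension of an empty mask")
    if box_sizes is None:
        box_sizes = default_box_sizes(mask.shape)
    sizes = np.asarray(sorted(int(s) for s in box_sizes))
    if len(sizes) < 3:
        raise ValueError(f"need at least 3 box sizes, got {len(sizes)}")
    if sizes[0] < 1 or len(np.unique(sizes)) != len(sizes):
        raise ValueError("box sizes must be distinct positive integers")

    counts = np.array([_count_boxes(mask, s) for s in sizes], dtype=np.float64)
    log_s = np.log(sizes.astype(np.float64))
    log_n = np.log(counts)
    slope, intercept = np.polyfit(log_s, log_n, 1)
    fitted = slope * log_s + intercept
    ss_res = float(((log_n - fitted) ** 2).sum())
    ss_tot = float(((log_n - log_n.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if r_squared < 0.9:
        logger.warning("box-counting fit is poor (r^2 = %.3f)", r_squared)
    return FractalResult(fd=float(-slope), box_sizes=sizes, box_counts=counts.astype(int),
                         r_squared=r_squared)
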