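"""Strut analysis of the binary mask / skeleton pair.

After thinning, each skeleton pixel is classified by its number of
8-connected skeleton neighbours: a terminus (free end) has exactly one, a
strut pixel exactly two, a node (crossing point) three or more, and an
isolated pixel none.  Together with the high-density area (HDA, foreground
pixel count), its periphery (foreground pixels touching background) and the
total strut length (TSL, skeleton length), these yield the fourteen ratio
features used to compare trabecular architecture between groups:

    HDA/total area, periphery/total area, periphery/HDA, TSL/HDA,
    TSL/total area, Tm/cm^2, Tm/TSL, Tm/periphery, Tm/HDA,
    Nd/cm^2, Nd/TSL, Nd/periphery, Nd/HDA, Nd/Tm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .images import BinaryImage, SkeletonImage

__all__ = [
    "PixelClassMap",
    "StrutFeatures",
    "RATIO_NAMES",
    "classify_pixels",
    "strut_metrics",
    "strut_ratios",
]

logger = logging.getLogger(__name__)

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity

RATIO_NAMES = (
    "hda/total_area",
    "periphery/total_area",
    "periphery/hda",
    "tsl/hda",
    "tsl/total_area",
    "n_tm/cm2",
    "n_tm/tsl",
    "n_tm/periphery",
    "n_tm/hda",
    "n_nd/cm2",
    "n_nd/tsl",
    "n_nd/periphery",
    "n_nd/hda",
    "n_nd/n_tm",
)


@dataclass
class PixelClassMap:
    """Per-pixel skeleton classes (8-connectivity neighbour counts)."""

    terminus: np.ndarray  # exactly 1 skeleton neighbour
    strut: np.ndarray     # exactly 2
    node: np.ndarray      # >= 3
    isolated: np.ndarray  # 0

    @property
    def n_terminus(self) -> int:
        return int(self.terminus.sum())

    @property
    def n_node_pixels(self) -> int:
        return int(self.node.sum())

    @property
    def n_node_clusters(self) -> int:
        """Number of 4-connected clusters of node pixels (junction entities)."""
        return int(ndi.label(self.node, _CROSS)[1])


def classify_pixels(skeleton: SkeletonImage) -> PixelClassMap:
    """Classify every skeleton pixel by its 8-neighbourhood skeleton count."""
    sk = skeleton.mask
    neighbours = ndi.convolve(sk.astype(np.int8), _NEIGHBOR_KERNEL, mode="constant", cval=0)
    return PixelClassMap(
        terminus=sk & (neighbours == 1),
        strut=sk & (neighbours == 2),
        node=sk & (neighbours >= 3),
        isolated=sk & (neighbours == 0),
    )


@dataclass
class StrutFeatures:
    """Raw strut counts for one ROI (areas also in cm^2 via pixel size)."""

    total_area_px: int
    hda_px: int
    periphery_px: int
    tsl_px: float
    n_tm: int
    n_nd: int
    pixel_size_mm: float

    @property
    def total_area_cm2(self) -> float:
        return self.total_area_px * (self.pixel_size_mm / 10.0) ** 2


def _weighted_skeleton_length(sk: np.ndarray) -> float:
    """Chain-code length: 1 per axial link, sqrt(2) per diagonal link, 1 per
    isolated pixel.  Each link between two skeleton pixels is counted once."""
    axial = int((sk[:, :-1] & sk[:, 1:]).sum() + (sk[:-1, :] & sk[1:, :]).sum())
    diag = int((sk[:-1, :-1] & sk[1:, 1:]).sum() + (sk[:-1, 1:] & sk[1:, :-1]).sum())
    neighbours = ndi.convolve(sk.astype(np.int8), _NEIGHBOR_KERNEL, mode="constant", cval=0)
    isolated = int((sk & (neighbours == 0)).sum())
    return axial + math.sqrt(2.0) * diag + isolated


def strut_metrics(
    binary: BinaryImage,
    skeleton: SkeletonImage,
    node_mode: Literal["cluster", "pixel"] = "cluster",
    tsl_weighted: bool = False,
) -> StrutFeatures:
    """Strut counts of a binary mask and its skeleton.

    Periphery pixels are foreground pixels with at least one background
    4-neighbour; the image border counts as background.  TSL defaults to the
    skeleton pixel count (``tsl_weighted=True`` switches to sqrt(2)-weighted
    chain-code length).  ``node_mode='cluster'`` counts each 4-connected
    cluster of node pixels as one crossing point; ``'pixel'`` counts pixels.
    """
    if binary.shape != skeleton.shape:
        raise ValueError(f"shape mismatch: binary {binary.shape} vs skeleton {skeleton.shape}")
    if binary.pixel_size_mm != skeleton.pixel_size_mm:
        raise ValueError("binary and skeleton pixel sizes differ")
    fg = binary.mask
    interior = ndi.binary_erosion(fg, _CROSS, border_value=0)
    classes = classify_pixels(skeleton)
    n_nd = classes.n_node_clusters if node_mode == "cluster" else classes.n_node_pixels
    sk = skeleton.mask
    tsl = _weighted_skeleton_length(sk) if tsl_weighted else float(sk.sum())
    return StrutFeatures(
        total_area_px=int(fg.size),
        hda_px=int(fg.sum()),
        periphery_px=int((fg & ~interior).sum()),
        tsl_px=tsl,
        n_tm=classes.n_terminus,
        n_nd=n_nd,
        pixel_size_mm=binary.pixel_size_mm,
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("ratio %s has a zero denominator; reported as NaN", name)
        return float("nan")
    return num / den


def strut_ratios(features: StrutFeatures) -> dict[str, float]:
    """The fourteen strut ratio features, keyed by :data:`RATIO_NAMES`.

    Any ratio with a zero denominator is reported as NaN (and logged), never
    silently as 0.
    """
    if features.total_area_px <= 0:
        raise ValueError("total_area_px must be positive")
    f = features
    area_cm2 = f.total_area_cm2
    values = {
        "hda/total_area": f.hda_px / f.total_area_px,
        "periphery/total_area": f.periphery_px / f.total_area_px,
        "periphery/hda": _safe_ratio(f.periphery_px, f.hda_px, "periphery/hda"),
        "tsl/hda": _safe_ratio(f.tsl_px, f.hda_px, "tsl/hda"),
        "tsl/total_area": f.tsl_px / f.total_area_px,
        "n_tm/cm2": f.n_tm / area_cm2,
        "n_tm/tsl": _safe_ratio(f.n_tm, f.tsl_px, "n_tm/tsl"),
        "n_tm/periphery": _safe_ratio(f.n_tm, f.periphery_px, "n_tm/periphery"),
        "n_tm/hda": _safe_ratio(f.n_tm, f.hda_px, "n_tm/hda"),
        "n_nd/cm2": f.n_nd / area_cm2,
        "n_nd/tsl": _safe_ratio(f.n_nd, f.tsl_px, "n_nd/tsl"),
        "n_nd/periphery": _safe_ratio(f.n_nd, f.periphery_px, "n_nd/periphery"),
        "n_nd/hda": _safe_ratio(f.n_nd, f.hda_px, "n_nd/hda"),
        "n_nd/n_tm": _safe_ratio(f.n_nd, f.n_tm, "n_nd/n_tm"),
    }
    return {name: float(values[name]) for name in RATIO_NAMES}
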