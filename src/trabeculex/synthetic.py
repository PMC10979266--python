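"""Synthetic trabecular-texture ROIs and cortical-landmark fixtures.

Real panoramic radiographs of the study cohorts are not available, so every
downstream stage is exercised on synthetic data with known ground truth.

The trabecular model is a thresholded smoothed Gaussian random field: white
noise smoothed with an isotropic Gaussian kernel of physical scale
``correlation_length_mm`` and cut at the ``(1 - bone_fraction)`` quantile.
This produces a connected strut-like network whose density (bone fraction)
and characteristic spacing are controlled independently — the two knobs that
separate pre- and post-menopausal-like texture in the screening literature.
Bone is rendered bright on a dark background (radiopaque = high intensity),
then degraded with a planar illumination gradient (the large-scale density
variation of panoramic radiographs) and i.i.d. Gaussian noise.

Cortical-landmark fixtures are parallel border polylines a known
perpendicular distance apart, optionally sloped and rigidly jittered, so the
true mental index (MI) and panoramic mandibular index (PMI) are known by
construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .images import GrayImage
from .morphometrics import LandmarkSet

__all__ = [
    "TrabecularParams",
    "GroundTruth",
    "CohortSpec",
    "CortexTruth",
    "generate_trabecular_roi",
    "generate_cohort",
    "generate_cortex_landmarks",
]

# Intensity levels for rendered bone / marrow background, chosen so the
# default gradient + noise stay inside [0, 255] without heavy clipping.
_BONE_LEVEL = 190.0
_MARROW_LEVEL = 65.0


@dataclass(frozen=True)
class TrabecularParams:
    """Generator parameters for one 5 x 5 mm trabecular ROI.

    bone_fraction
        Target foreground (bone) fraction of the ground-truth mask, in (0, 1).
    correlation_length_mm
        Gaussian smoothing scale of the random field; sets trabecular spacing.
    gradient_amplitude
        Peak-to-peak amplitude (gray levels) of the planar illumination drift.
    noise_sd
        Standard deviation of additive Gaussian pixel noise (gray levels).
    pixel_size_mm
        Physical size of one pixel; 0.1 mm is typical of panoramic detectors.
    roi_size_mm
        Side of the square ROI; the study protocol uses 5 mm.
    seed
        Seed of the per-image random stream.
    """

    bone_fraction: float = 0.48
    correlation_length_mm: float = 0.4
    gradient_amplitude: float = 30.0
    noise_sd: float = 8.0
    pixel_size_mm: float = 0.1
    roi_size_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.bone_fraction < 1.0:
            raise ValueError(f"bone_fraction must lie strictly in (0, 1), got {self.bone_fraction}")
        if self.correlation_length_mm <= 0:
            raise ValueError("correlation_length_mm must be positive")
        if not 0.0 <= self.gradient_amplitude <= 255.0:
            raise ValueError("gradient_amplitude must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pixel_size_mm <= 0 or self.roi_size_mm <= 0:
            raise ValueError("pixel_size_mm and roi_size_mm must be positive")
        n = self.roi_size_mm / self.pixel_size_mm
        if abs(n - round(n)) > 1e-9 or round(n) < 16:
            raise ValueError(
                "roi_size_mm / pixel_size_mm must be an integer pixel count >= 16, "
                f"got {n}"
            )

    @property
    def n_px(self) -> int:
        return int(round(self.roi_size_mm / self.pixel_size_mm))


@dataclass
class GroundTruth:
    """Noiseless truth accompanying one generated ROI."""

    mask: np.ndarray  # bool, True = bone
    params: TrabecularParams

    @property
    def bone_fraction_observed(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort of generated ROIs with deterministic per-image seeds."""

    group_a: TrabecularParams
    group_b: TrabecularParams
    n_per_group: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")


def generate_trabecular_roi(params: TrabecularParams) -> tuple[GrayImage, GroundTruth]:
    """Generate one trabecular ROI and its ground-truth bone mask.

    The field is seeded white noise smoothed at ``correlation_length_mm`` and
    thresholded at the value of its ``round(bone_fraction * N)``-th largest
    pixel, so the observed mask fraction matches ``bone_fraction`` to within
    half a pixel of the total count.
    """
    n = params.n_px
    rng = np.random.default_rng(params.seed)
    field = ndi.gaussian_filter(
        rng.standard_normal((n, n)),
        sigma=params.correlation_length_mm / params.pixel_size_mm,
        mode="reflect",
    )
    if field.std() < 1e-12:
        raise ValueError("degenerate random field: constant after smoothing")

    total = n * n
    k = int(round(params.bone_fraction * total))
    if not 1 <= k <= total - 1:
        raise ValueError("bone_fraction too extreme for this ROI size")
    # threshold = k-th largest field value -> mask has exactly k pixels
    threshold = np.partition(field.ravel(), total - k)[total - k]
    mask = field >= threshold

    rendered = np.where(mask, _BONE_LEVEL, _MARROW_LEVEL)
    cols = np.arange(n, dtype=np.float64)
    rendered = rendered + params.gradient_amplitude * (cols / (n - 1) - 0.5)[None, :]
    if params.noise_sd > 0:
        rendered = rendered + rng.normal(0.0, params.noise_sd, size=(n, n))
    pixels = np.clip(np.round(rendered), 0, 255)
    return GrayImage(pixels, params.pixel_size_mm), GroundTruth(mask=mask, params=params)


def generate_cohort(spec: CohortSpec) -> list[tuple[GrayImage, GroundTruth, str]]:
    """Generate ``2 * n_per_group`` labelled ROIs.

    Per-image seeds are ``base_seed + i`` (group A takes offsets
    ``0 .. n-1``, group B ``n .. 2n-1``) so cohorts are fully reproducible.
    """
    out: list[tuple[GrayImage, GroundTruth, str]] = []
    for i in range(spec.n_per_group):
        params = dataclasses.replace(spec.group_a, seed=spec.base_seed + i)
        img, truth = generate_trabecular_roi(params)
        out.append((img, truth, "A"))
    for i in range(spec.n_per_group):
        params = dataclasses.replace(spec.group_b, seed=spec.base_seed + spec.n_per_group + i)
        img, truth = generate_trabecular_roi(params)
        out.append((img, truth, "B"))
    return out


@dataclass
class CortexTruth:
    """True index values built into a cortical-landmark fixture."""

    mi_mm: float
    pmi: float
    params: dict = field(default_factory=dict)


def generate_cortex_landmarks(
    thickness_mm: float,
    reference_height_mm: float,
    border_slope_deg: float = 0.0,
    pixel_size_mm: float = 0.1,
    seed: int = 0,
) -> tuple[LandmarkSet, CortexTruth]:
    """Cortical-border fixture with known MI and PMI.

    Three parallel polylines — inferior border, endosteal border at
    perpendicular distance ``thickness_mm``, and cortex upper edge at
    ``reference_height_mm`` — plus a mental-foramen point above them.  The
    whole set is rotated by ``border_slope_deg`` and rigidly jittered from
    the seed, so true MI = ``thickness_mm`` and true PMI =
    ``thickness_mm / reference_height_mm`` regardless of pose.
    """
    if thickness_mm <= 0 or reference_height_mm <= 0:
        raise ValueError("thickness_mm and reference_height_mm must be positive")
    if thickness_mm >= reference_height_mm:
        raise ValueError(
            f"thickness_mm ({thickness_mm}) must be smaller than "
            f"reference_height_mm ({reference_height_mm})"
        )

    rng = np.random.default_rng(seed)
    xs = np.linspace(-12.0, 12.0, 9)
    inferior = np.column_stack([xs, np.zeros_like(xs)])
    endosteal = np.column_stack([xs, np.full_like(xs, thickness_mm)])
    upper = np.column_stack([xs, np.full_like(xs, reference_height_mm)])
    foramen = np.array([rng.uniform(-2.0, 2.0), reference_height_mm + 2.0])

    theta = np.deg2rad(border_slope_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shift = rng.uniform(-5.0, 5.0, size=2)

    def _pose(pts: np.ndarray) -> np.ndarray:
        return pts @ rot.T + shift

    landmarks = LandmarkSet(
        inferior_border=_pose(inferior),
        endosteal_border=_pose(endosteal),
        cortex_upper_edge=_pose(upper),
        mental_foramen=_pose(foramen[None, :])[0],
        side="left",
        pixel_size_mm=pixel_size_mm,
    )
    truth = CortexTruth(
        mi_mm=thickness_mm,
        pmi=thickness_mm / reference_height_mm,
        params={
            "thickness_mm": thickness_mm,
            "reference_height_mm": reference_height_mm,
            "border_slope_deg": border_slope_deg,
            "seed": seed,
        },
    )
    return landmarks, truth
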