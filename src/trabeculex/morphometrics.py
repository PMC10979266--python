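"""Radio-morphometric indices of the mandible: MI, PMI and the MCI classes.

The mental index (MI) is the cortical thickness at the mental foramen,
measured perpendicular to the inferior border of the mandible; values above
3.1 mm are considered normal.  The panoramic mandibular index (PMI) divides
that thickness by a reference height measured along the same perpendicular;
values above 0.3 are normal.  The mandibular cortical index (MCI, Klemetti
C1/C2/C3) is a visual grading and is consumed here as an annotation, never
computed from pixels.

Landmarks are polylines in mm coordinates.  Geometry is delegated to
shapely: the measurement line is the perpendicular to the inferior border's
nearest segment through the foramen, and each index is a distance between
its intersections with two border polylines.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "LandmarkSet",
    "MorphometricRecord",
    "MorphometricError",
    "MI_NORMAL_MM",
    "PMI_NORMAL",
    "MCI_CLASSES",
    "mental_index",
    "panoramic_mandibular_index",
    "validate_mci",
    "mci_frequency",
    "assess",
    "load_landmarks",
]

MI_NORMAL_MM = 3.1
PMI_NORMAL = 0.3
MCI_CLASSES = ("C1", "C2", "C3")


class MorphometricError(ValueError):
    """Raised when a measurement cannot be constructed from the landmarks."""


def _as_polyline(pts, name: str) -> np.ndarray:
    a = np.asarray(pts, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] != 2 or a.shape[0] < 2:
        raise ValueError(f"{name} must be an (N, 2) polyline with N >= 2")
    return a


@dataclass
class LandmarkSet:
    """Cortical-border annotations for one hemi-mandible, in mm coordinates."""

    inferior_border: np.ndarray
    endosteal_border: np.ndarray
    mental_foramen: np.ndarray
    cortex_upper_edge: Optional[np.ndarray] = None
    side: str = "left"
    pixel_size_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.inferior_border = _as_polyline(self.inferior_border, "inferior_border")
        self.endosteal_border = _as_polyline(self.endosteal_border, "endosteal_border")
        if self.cortex_upper_edge is not None:
            self.cortex_upper_edge = _as_polyline(self.cortex_upper_edge, "cortex_upper_edge")
        self.mental_foramen = np.asarray(self.mental_foramen, dtype=np.float64).reshape(2)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


def _nearest_segment_tangent(polyline: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Unit direction of the polyline segment nearest to ``point``."""
    p0, p1 = polyline[:-1], polyline[1:]
    seg = p1 - p0
    seg_len2 = (seg**2).sum(axis=1)
    t = np.clip(((point - p0) * seg).sum(axis=1) / np.where(seg_len2 > 0, seg_len2, 1.0), 0, 1)
    closest = p0 + t[:, None] * seg
    i = int(np.argmin(((closest - point) ** 2).sum(axis=1)))
    d = seg[i]
    norm = np.hypot(*d)
    if norm == 0:
        raise MorphometricError("nearest inferior-border segment is degenerate")
    return d / norm


def _perpendicular_hit(polyline: np.ndarray, origin: np.ndarray, normal: np.ndarray,
                       name: str) -> np.ndarray:
    """Nearest intersection of the measurement line with a border polyline."""
    span = 4.0 * (np.abs(polyline - origin).max() + 1.0)
    line = LineString([origin - span * normal, origin + span * normal])
    hit = line.intersection(LineString(polyline))
    if hit.is_empty:
        raise MorphometricError(f"perpendicular through the foramen misses {name}")
    pts = []
    for geom in getattr(hit, "geoms", [hit]):
        pts.extend(geom.coords)
    pts = np.asarray(pts, dtype=np.float64)
    return pts[np.argmin(((pts - origin) ** 2).sum(axis=1))]


def _measurement_points(landmarks: LandmarkSet):
    tangent = _nearest_segment_tangent(landmarks.inferior_border, landmarks.mental_foramen)
    normal = np.array([-tangent[1], tangent[0]])
    p_inf = _perpendicular_hit(landmarks.inferior_border, landmarks.mental_foramen,
                               normal, "inferior_border")
    p_end = _perpendicular_hit(landmarks.endosteal_border, landmarks.mental_foramen,
                               normal, "endosteal_border")
    return normal, p_inf, p_end


def mental_index(landmarks: LandmarkSet) -> float:
    """Cortical thickness (mm) at the foramen, perpendicular to the inferior border."""
    _, p_inf, p_end = _measurement_points(landmarks)
    return float(np.hypot(*(p_end - p_inf)))


def panoramic_mandibular_index(
    landmarks: LandmarkSet,
    reference: Literal["cortex_upper_edge", "foramen"] = "cortex_upper_edge",
) -> float:
    """Cortical thickness divided by a reference height along the same perpendicular.

    ``reference='cortex_upper_edge'`` divides by the distance from the
    inferior border to the upper edge of the cortex (the study's wording);
    ``reference='foramen'`` uses the classical inferior-border-to-foramen
    distance.
    """
    normal, p_inf, p_end = _measurement_points(landmarks)
    mi = float(np.hypot(*(p_end - p_inf)))
    if reference == "foramen":
        ref_point = landmarks.mental_foramen
    elif reference == "cortex_upper_edge":
        if landmarks.cortex_upper_edge is None:
            raise MorphometricError("cortex_upper_edge polyline is required for PMI")
        ref_point = _perpendicular_hit(landmarks.cortex_upper_edge, landmarks.mental_foramen,
                                       normal, "cortex_upper_edge")
    else:
        raise ValueError(f"unknown reference {reference!r}")
    ref = float(np.hypot(*(ref_point - p_inf)))
    if ref <= 1e-12:
        raise MorphometricError("degenerate (zero) PMI reference distance")
    pmi = mi / ref
    if not 0.0 <= pmi <= 1.0:
        warnings.warn(f"PMI {pmi:.3f} outside the expected [0, 1] range", stacklevel=2)
    return pmi


def validate_mci(label: str):
    """Canonicalize a Klemetti cortical-erosion class label."""
    canonical = str(label).strip().upper()
    if canonical not in MCI_CLASSES:
        raise ValueError(f"invalid MCI class {label!r}; valid classes are {MCI_CLASSES}")
    return canonical


def mci_frequency(labels: Iterable[str]) -> dict[str, int]:
    """Class frequency table of a cohort of MCI annotations."""
    counts = Counter(validate_mci(lab) for lab in labels)
    return {c: counts.get(c, 0) for c in MCI_CLASSES}


@dataclass
class MorphometricRecord:
    """MI/PMI measurements with normal-range flags and the MCI annotation."""

    mi_mm: float
    pmi: float
    mci: Optional[str] = None
    mi_normal: bool = False
    pmi_normal: bool = False


def assess(
    landmarks: LandmarkSet,
    mci: Optional[str] = None,
    pmi_reference: Literal["cortex_upper_edge", "foramen"] = "cortex_upper_edge",
) -> MorphometricRecord:
    """Measure MI and PMI and flag them against the normal-range cut-offs."""
    mi = mental_index(landmarks)
    pmi = panoramic_mandibular_index(landmarks, reference=pmi_reference)
    return MorphometricRecord(
        mi_mm=mi,
        pmi=pmi,
        mci=validate_mci(mci) if mci is not None else None,
        mi_normal=mi > MI_NORMAL_MM,
        pmi_normal=pmi > PMI_NORMAL,
    )


def load_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file.

    Expected keys: ``inferior_border``, ``endosteal_border``,
    ``mental_foramen`` and optionally ``cortex_upper_edge``, ``side``,
    ``pixel_size_mm``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    return LandmarkSet(
        inferior_border=raw["inferior_border"],
        endosteal_border=raw["endosteal_border"],
        mental_foramen=raw["mental_foramen"],
        cortex_upper_edge=raw.get("cortex_upper_edge"),
        side=raw.get("side", "left"),
        pixel_size_mm=raw.get("pixel_size_mm"),
    )
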