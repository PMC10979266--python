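"""Pipeline driver: configuration, per-image feature extraction, cohort runs
and provenance logging.

``run_pipeline`` ties the stages together: preprocess each ROI image,
extract GLCM / fractal / strut features (plus MI and PMI where landmark
files are given), assemble the feature table, and compare the two groups.
Images that fail to load or process are skipped with a logged warning; the
run fails only if nothing could be processed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .images import GrayImage, read_gray, write_gray, write_mask
from .morphometrics import assess, load_landmarks
from .preprocess import ChainConfig, ChainResult, RoiSpec, run_chain
from .stats import compare_groups
from .strut import strut_metrics, strut_ratios
from .texture import box_counting_fd, compute_glcm, default_box_sizes, glcm_features

__all__ = ["RunConfig", "extract_features", "run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_PARTIAL = 1
EXIT_FATAL = 2


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, serialized into each output's provenance."""

    chain: ChainConfig = ChainConfig()
    glcm_offset: tuple[int, int] = (0, 1)
    glcm_levels: int = 256
    glcm_symmetric: bool = True
    glcm_input: str = "corrected"  # 'corrected' grayscale or raw 'roi'
    fd_box_sizes: Optional[tuple[int, ...]] = None
    node_mode: str = "cluster"
    tsl_weighted: bool = False
    alpha: float = 0.05
    pmi_reference: str = "cortex_upper_edge"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chain"] = dataclasses.asdict(self.chain)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        chain = ChainConfig(**raw.pop("chain", {}))
        if "glcm_offset" in raw:
            raw["glcm_offset"] = tuple(raw["glcm_offset"])
        if raw.get("fd_box_sizes") is not None:
            raw["fd_box_sizes"] = tuple(raw["fd_box_sizes"])
        return cls(chain=chain, **raw)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def extract_features(
    image: GrayImage,
    spec: Optional[RoiSpec] = None,
    config: RunConfig = RunConfig(),
) -> tuple[dict[str, float], ChainResult]:
    """Run the chain on one ROI and compute the full feature vector."""
    chain = run_chain(image, spec, config.chain)
    glcm_src = chain.corrected if config.glcm_input == "corrected" else chain.roi
    glcm = compute_glcm(glcm_src, offset=config.glcm_offset, levels=config.glcm_levels,
                        symmetric=config.glcm_symmetric)
    tex = glcm_features(glcm)
    sizes = config.fd_box_sizes or default_box_sizes(chain.skeleton.shape)
    fractal = box_counting_fd(chain.skeleton, sizes)
    metrics = strut_metrics(chain.binary, chain.skeleton, node_mode=config.node_mode,
                            tsl_weighted=config.tsl_weighted)
    features: dict[str, float] = {
        "fd": fractal.fd,
        "fd_r_squared": fractal.r_squared,
        "contrast": tex.contrast,
        "correlation": tex.correlation,
        "energy": tex.energy,
        "homogeneity": tex.homogeneity,
    }
    features.update(strut_ratios(metrics))
    return features, chain


@dataclass
class PipelineResult:
    features: pd.DataFrame
    comparison: Optional[pd.DataFrame]
    provenance: dict
    exit_code: int
    warnings: list[str] = field(default_factory=list)


def _sha1_file(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:12]


def run_pipeline(
    manifest: pd.DataFrame,
    config: RunConfig,
    out_dir: Optional[Path] = None,
    pixel_size_mm: float = 0.1,
    write_intermediates: bool = False,
) -> PipelineResult:
    """Process a cohort manifest end to end.

    ``manifest`` needs columns ``image`` (PNG/TIFF path) and ``group``
    ('A'/'B'); optional columns: ``image_id``, ``roi`` (label), ``roi_spec``
    (JSON path), ``landmarks`` (JSON path), ``mci``, ``pixel_size_mm``.
    Writes ``features.csv``, ``comparison.csv`` and ``provenance.json``
    under ``out_dir`` when given.
    """
    records: list[dict] = []
    warnings_log: list[str] = []
    stage_log: list[dict] = []

    for idx, row in manifest.iterrows():
        path = Path(row["image"])
        image_id = str(row.get("image_id", path.stem))
        try:
            px = float(row.get("pixel_size_mm", pixel_size_mm) or pixel_size_mm)
            image = read_gray(path, px)
            spec = None
            if isinstance(row.get("roi_spec"), str) and row["roi_spec"]:
                with open(row["roi_spec"]) as fh:
                    spec = RoiSpec(**json.load(fh))
            features, chain = extract_features(image, spec, config)
            rec = {
                "image_id": image_id,
                "roi": str(row.get("roi", spec.label if spec else "ROI1")),
                "group": str(row["group"]),
                **features,
                "config_hash": config.hash,
            }
            if isinstance(row.get("landmarks"), str) and row["landmarks"]:
                lm = load_landmarks(row["landmarks"])
                mci = row.get("mci") if isinstance(row.get("mci"), str) else None
                morpho = assess(lm, mci=mci, pmi_reference=config.pmi_reference)
                rec.update(mi_mm=morpho.mi_mm, pmi=morpho.pmi, mci=morpho.mci,
                           mi_normal=morpho.mi_normal, pmi_normal=morpho.pmi_normal)
            records.append(rec)
            stage_log.append({
                "image_id": image_id,
                "input": str(path),
                "input_sha1": _sha1_file(path),
                "status": "ok",
            })
            if write_intermediates and out_dir is not None:
                stem = Path(out_dir) / image_id
                write_gray(f"{stem}_corrected.png", chain.corrected)
                write_mask(f"{stem}_binary.png", chain.binary.mask)
                write_mask(f"{stem}_skeleton.png", chain.skeleton.mask)
        except Exception as exc:  # noqa: BLE001 - skip-and-log per image
            msg = f"{image_id}: skipped ({exc})"
            logger.warning(msg)
            warnings_log.append(msg)
            stage_log.append({"image_id": image_id, "input": str(path),
                              "status": "skipped", "error": str(exc)})

    if not records:
        return PipelineResult(
            features=pd.DataFrame(), comparison=None,
            provenance={"stages": stage_log, "config": config.to_dict()},
            exit_code=EXIT_FATAL, warnings=warnings_log,
        )

    features_df = pd.DataFrame(records).sort_values(["group", "image_id"]).reset_index(drop=True)
    comparison = None
    try:
        numeric = [c for c in features_df.columns
                   if c not in ("image_id", "mci", "config_hash", "mi_normal", "pmi_normal",
                                "fd_r_squared")
                   and features_df[c].dtype != object]
        comparison = compare_groups(features_df[["group", "roi", *
                                                 [c for c in numeric if c not in ("group",)]]],
                                    alpha=config.alpha)
    except ValueError as exc:
        msg = f"group comparison skipped: {exc}"
        logger.warning(msg)
        warnings_log.append(msg)

    provenance = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "version": __version__,
        "platform": platform.platform(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "config_hash": config.hash,
        "stages": stage_log,
        "warnings": warnings_log,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features_df.to_csv(out / "features.csv", index=False)
        if comparison is not None:
            comparison.to_csv(out / "comparison.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)

    exit_code = EXIT_OK if not warnings_log else EXIT_PARTIAL
    return PipelineResult(features=features_df, comparison=comparison,
                          provenance=provenance, exit_code=exit_code,
                          warnings=warnings_log)
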