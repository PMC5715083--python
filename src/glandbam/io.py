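"""File I/O, configuration and the end-to-end pipeline.

The pipeline ties the library together: label masks -> per-gland aberrance
table (glands.csv) -> per-image features before and after postprocessing
(features_pre.csv / features_post.csv) -> cross-validated grading report
(report.json).  Configuration is a nested YAML/JSON document mirroring the
config dataclasses; unknown keys are rejected and a config hash is recorded
in the outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aberrance import AberranceConfig, image_aberrance_table
from .exceptions import InvalidInputError, SchemaError, UndefinedFeatureError
from .features import (
    BASELINE_FEATURE_NAMES,
    BinConfig,
    ImageFeatures,
    PostprocessConfig,
    compute_image_features,
    postprocess_features,
)
from .grading import GradingConfig, cross_validate, evaluate_binary_views
from .synthetic import SyntheticConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_mask",
    "read_labels",
    "glands_to_frame",
    "features_to_frame",
    "run_pipeline",
]

VALID_LABELS = {"normal", "low_grade", "high_grade"}


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for the whole pipeline; all fields have defaults."""

    aberrance: AberranceConfig = field(default_factory=AberranceConfig)
    bins: BinConfig = field(default_factory=BinConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    grading: GradingConfig = field(default_factory=GradingConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(sections)
        if unknown:
            raise SchemaError(f"unknown config sections {sorted(unknown)}")
        kwargs = {}
        for name, spec in sections.items():
            section = data.get(name, {})
            if not isinstance(section, dict):
                raise SchemaError(f"config section {name!r} must be a mapping")
            section_cls = spec.default_factory  # the config dataclass itself
            known = {f.name for f in dataclasses.fields(section_cls())}
            bad = set(section) - known
            if bad:
                raise SchemaError(f"unknown keys {sorted(bad)} in config section {name!r}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            kwargs[name] = section_cls(**coerced)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise SchemaError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 2-D integer label mask from PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        mask = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        mask = iio.imread(path)
    mask = np.asarray(mask)
    if mask.ndim == 3 and mask.shape[2] in (3, 4):
        # accept grayscale saved with redundant channels
        if not np.all(mask[..., 0] == mask[..., 1]):
            raise InvalidInputError(f"{path} is not a label image")
        mask = mask[..., 0]
    if mask.ndim != 2:
        raise InvalidInputError(f"{path}: mask must be 2-D, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise InvalidInputError(f"{path}: mask must be integer-typed, got {mask.dtype}")
    return mask


def read_labels(path: str | Path) -> dict[str, str]:
    """Read the per-image grade file: CSV with header ``image_id,label``.

    Duplicate image ids keep the last row (with a warning); unknown label
    tokens raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"image_id", "label"}
    if not required.issubset(df.columns):
        raise SchemaError(f"labels file needs columns {sorted(required)}, got {list(df.columns)}")
    out: dict[str, str] = {}
    for row in df.itertuples(index=True):
        if row.label not in VALID_LABELS:
            raise SchemaError(
                f"unknown label {row.label!r} for image {row.image_id!r} (row {row.Index})"
            )
        if row.image_id in out:
            logger.warning("duplicate image_id %s in labels file; last row wins", row.image_id)
        out[row.image_id] = row.label
    return out


def glands_to_frame(records_by_image: dict[str, list]) -> pd.DataFrame:
    """Flatten per-image gland records into the glands.csv schema."""
    rows = []
    for image_id, records in records_by_image.items():
        for r in records:
            rows.append({
                "image_id": image_id,
                "gland_id": r.gland_id,
                "area": r.area,
                "centroid_x": r.centroid[0],
                "centroid_y": r.centroid[1],
                "touches_border": r.touches_border,
                "aberrance": np.nan if r.aberrance is None else r.aberrance,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            })
    return pd.DataFrame(rows, columns=[
        "image_id", "gland_id", "area", "centroid_x", "centroid_y",
        "touches_border", "aberrance", "excluded", "exclusion_reason",
    ])


def features_to_frame(features: list[ImageFeatures]) -> pd.DataFrame:
    """Stack per-image features into the features.csv schema."""
    rows = []
    for f in features:
        row = {
            "image_id": f.image_id,
            "n_glands": f.n_glands,
            "mean_bam": f.mean_bam,
            "bam_entropy": f.bam_entropy,
            "regularity_index": f.regularity_index,
        }
        if f.baseline is not None:
            for name in BASELINE_FEATURE_NAMES:
                row[name] = f.baseline[name]
        row["label"] = f.label
        row["postprocessed"] = f.postprocessed
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    mask_dir: str | Path,
    labels_file: str | Path | None,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    include_baseline: bool = False,
) -> dict:
    """Masks -> gland table -> features -> grading report, written to out_dir.

    Per-image failures are logged and skipped.  Writes glands.csv,
    features_pre.csv, features_post.csv and report.json (which records the
    config hash and seed).  Returns the report dictionary.
    """
    mask_dir = Path(mask_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = read_labels(labels_file) if labels_file else {}
    paths = sorted(
        p for p in mask_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise InvalidInputError(f"no mask images found in {mask_dir}")

    records_by_image: dict[str, list] = {}
    feats_pre: list[ImageFeatures] = []
    feats_post: list[ImageFeatures] = []
    for path in paths:
        image_id = path.stem
        label = labels.get(image_id, "unknown")
        if labels and image_id not in labels:
            logger.warning("image %s missing from labels file; graded as unknown", image_id)
        try:
            mask = read_mask(path)
            records = image_aberrance_table(
                mask, image_id=image_id, config=config.aberrance,
                include_baseline=include_baseline,
            )
            pre = compute_image_features(
                records, config.bins, include_baseline=include_baseline, label=label
            )
            records, post = postprocess_features(records, pre, config.postprocess, config.bins)
        except (InvalidInputError, UndefinedFeatureError) as exc:
            logger.warning("image %s skipped: %s", image_id, exc)
            continue
        records_by_image[image_id] = records
        feats_pre.append(pre)
        feats_post.append(post)
        logger.info(
            "image %s: %d glands, %d excluded, mean_bam=%.4f ri=%.3f",
            image_id, len(records), sum(r.excluded for r in records),
            post.mean_bam, post.regularity_index,
        )

    if not feats_post:
        raise InvalidInputError("no image produced usable features")

    glands = glands_to_frame(records_by_image)
    pre_df = features_to_frame(feats_pre)
    post_df = features_to_frame(feats_post)
    glands.to_csv(out / "glands.csv", index=False)
    pre_df.to_csv(out / "features_pre.csv", index=False)
    post_df.to_csv(out / "features_post.csv", index=False)

    report: dict = {
        "config_hash": config.config_hash,
        "seed": config.grading.seed,
        "n_images": len(post_df),
    }
    graded = post_df[post_df["label"].isin(VALID_LABELS)]
    n_classes = graded["label"].nunique()
    if n_classes >= 2:
        cv = cross_validate(graded, cfg=config.grading)
        report["cross_validation"] = cv.to_dict(percent=True)
        if config.grading.task == "three_class" and n_classes == 3:
            views = evaluate_binary_views(cv)
            report["binary_views"] = {
                view: {m: [v[0] * 100, v[1] * 100] for m, v in metrics.items()}
                for view, metrics in views.items()
            }
    else:
        logger.warning("fewer than 2 labelled classes; grading skipped")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
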