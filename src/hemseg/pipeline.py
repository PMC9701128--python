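"""End-to-end orchestration: configuration and the single-image detector."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import CandidateObject, HemsegError
from .preprocess import PreprocessParams, green_channel, preprocess_image
from .seeds import MatchedFilterParams, extract_seed_points
from .calibrate import calibrate
from .swat import segment_all
from .features import extract_conventional
from .classify import HE, TrainedModel, predict_many, LabeledExample

__all__ = ["PipelineConfig", "detect", "load_image", "save_overlay"]


@dataclass(frozen=True)
class SeedsConfig:
    sigma: float = 8.0
    kernel_radius: int = 16
    zero_mean: bool = True
    opening_radius: int = 4
    min_area: int = 5
    # two filter scales cover the configured lesion radius range
    sigmas: tuple[float, ...] = (6.0, 12.0)


@dataclass(frozen=True)
class CalibrateConfig:
    median_radius: int = 15
    erosion_radius: int = 3
    margin: int = 80


@dataclass(frozen=True)
class SwatConfig:
    max_iters: int = 50
    eta_min: float = 0.8
    r_max: int = 20
    dedup_iou: float = 0.8
    seed_pad: int = 12


@dataclass(frozen=True)
class ClassifyConfig:
    iou_min: float = 0.2
    kernel: str = "rbf"


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    seeds: SeedsConfig = field(default_factory=SeedsConfig)
    calibrate: CalibrateConfig = field(default_factory=CalibrateConfig)
    swat: SwatConfig = field(default_factory=SwatConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    rng_seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a nested YAML config, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sections = {
            "preprocess": PreprocessParams,
            "seeds": SeedsConfig,
            "calibrate": CalibrateConfig,
            "swat": SwatConfig,
            "classify": ClassifyConfig,
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key in ("rng_seed", "verbosity"):
                kwargs[key] = value
            elif key in sections:
                klass = sections[key]
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(
                        f"unknown keys in config section {key!r}: {sorted(unknown)}"
                    )
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = klass(**coerced)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)


def load_image(path: str | Path) -> np.ndarray:
    """Read an RGB image from PNG/JPEG/TIFF."""
    from PIL import Image, UnidentifiedImageError

    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except (UnidentifiedImageError, OSError) as exc:
        raise HemsegError(f"cannot read image file {path}: {exc}") from exc


def detect(
    image_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    model: TrainedModel | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full detection pipeline on one image.

    Returns a JSON-serializable report with every candidate's bounding box,
    area, center distance and (when a model is supplied) predicted label.
    With ``out_dir`` set, writes the report JSON, a candidate CSV and an
    overlay PNG with hemorrhage boxes.
    """
    rgb = load_image(image_path)
    enhanced = preprocess_image(rgb, config.preprocess)
    raw_green = green_channel(rgb)
    cc = config.calibrate
    products = calibrate(
        enhanced, green_raw=raw_green, median_radius=cc.median_radius,
        erosion_radius=cc.erosion_radius, margin=cc.margin,
    )
    sc = config.seeds
    # seeds come from the calibrated image: the whitened background restores
    # the dark-blob profile of rim lesions for the matched filter
    seeds = extract_seed_points(
        products.calibrated_image,
        MatchedFilterParams(sigma=sc.sigma, kernel_radius=sc.kernel_radius,
                            zero_mean=sc.zero_mean),
        opening_radius=sc.opening_radius,
        min_area=sc.min_area,
        sigmas=sc.sigmas,
    )
    objects = segment_all(
        products.calibrated_image, seeds, products.search_space,
        max_iters=config.swat.max_iters, dedup_iou=config.swat.dedup_iou,
        seed_pad=config.swat.seed_pad,
    )
    labels: list[str] | None = None
    if model is not None and objects:
        examples = [
            LabeledExample(features=extract_conventional(o, rgb), label="?", object_id=i)
            for i, o in enumerate(objects)
        ]
        labels = predict_many(model, examples)

    rows = []
    for i, obj in enumerate(objects):
        b = obj.final_bbox
        rows.append(
            {
                "object_id": i,
                "seed_id": obj.source_seed,
                "v1": b.v1, "v2": b.v2, "v3": b.v3, "v4": b.v4,
                "area": obj.area,
                "center_distance": round(obj.center_distance, 4),
                "converged": obj.converged,
                "label": labels[i] if labels is not None else None,
            }
        )
    report = {
        "image": str(image_path),
        "n_seeds": len(seeds),
        "n_candidates": len(objects),
        "candidates": rows,
        "n_hemorrhages": (
            sum(1 for r in rows if r["label"] == HE) if labels is not None else None
        ),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame(rows).to_csv(out / "candidates.csv", index=False)
        save_overlay(rgb, objects, labels, out / "overlay.png")
    return report


def save_overlay(
    rgb: np.ndarray,
    objects: list[CandidateObject],
    labels: list[str] | None,
    path: str | Path,
) -> None:
    """Overlay PNG: green boxes for candidates, red for predicted hemorrhages."""
    from PIL import Image, ImageDraw

    im = Image.fromarray(np.asarray(rgb, dtype=np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(im)
    for i, obj in enumerate(objects):
        b = obj.final_bbox
        is_he = labels is not None and labels[i] == HE
        color = (255, 32, 32) if is_he else (32, 255, 32)
        draw.rectangle([b.v1, b.v2, b.v3, b.v4], outline=color, width=2)
    im.save(path)
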