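"""SVM training, inference and evaluation for candidate windows.

Candidates from the segmentation stage are annotated against ground-truth
lesion masks by an IoU rule, featurized, and classified by a support vector
machine whose preprocessing (training-mean imputation of sentinel-flagged
blocks and per-feature z-normalization) is stored with the model.
Evaluation reports the 2x2 confusion counts with sensitivity
SE = 100*TP/(TP+FN) and specificity SP = 100*TN/(TN+FP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sklearn
from scipy import ndimage as ndi
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import EvalCounts, FeatureVector, HemsegError, ShapeError
from . import features as feat_mod
from .calibrate import calibrate
from .preprocess import PreprocessParams, green_channel, preprocess_image
from .seeds import MatchedFilterParams, extract_seed_points
from .swat import segment_all
from .synth import SynthSample

__all__ = [
    "HE",
    "NON_HE",
    "LabeledExample",
    "TrainedModel",
    "annotate_candidates",
    "train_svm",
    "predict",
    "evaluate",
    "run_experiment",
]

HE = "HE"
NON_HE = "non-HE"


class DegenerateTrainingError(HemsegError):
    """Training set contains a single class."""


class EmptyEvalError(HemsegError):
    """Nothing to evaluate."""


@dataclass(frozen=True)
class LabeledExample:
    features: FeatureVector
    label: str
    object_id: int = -1


@dataclass
class TrainedModel:
    """An SVM pipeline plus everything needed to apply it safely later."""

    pipeline: Pipeline
    feature_names: tuple[str, ...]
    kernel: str
    c: float
    gamma: float | str
    seed: int
    library_version: str = field(default_factory=lambda: sklearn.__version__)

    @property
    def imputation_means(self) -> np.ndarray:
        """Training means used to fill sentinel-flagged feature blocks."""
        return self.pipeline.named_steps["scaler"].mean_


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    return float(inter) / float(np.logical_or(a, b).sum())


def annotate_candidates(
    objects: Sequence, truth_mask: np.ndarray, iou_min: float = 0.2
) -> list[str]:
    """Label each candidate HE iff it overlaps any truth lesion at IoU >= iou_min.

    Truth lesions are the 8-connected components of ``truth_mask``; the rule
    is per-component, so a tight candidate on one lesion of many still
    counts.
    """
    truth = np.asarray(truth_mask, dtype=bool)
    lab, n = ndi.label(truth, structure=np.ones((3, 3)))
    labels: list[str] = []
    for obj in objects:
        if obj.mask.shape != truth.shape:
            raise ShapeError("candidate and truth masks must share a frame")
        hit = False
        overlapping = np.unique(lab[obj.mask])
        for comp in overlapping:
            if comp == 0:
                continue
            if _iou(obj.mask, lab == comp) >= iou_min:
                hit = True
                break
        labels.append(HE if hit else NON_HE)
    return labels


def _as_matrix(
    examples: Sequence[LabeledExample],
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    names = examples[0].features.names
    for ex in examples:
        if ex.features.names != names:
            raise ShapeError("feature names/order differ across examples")
    X = np.array([ex.features.values for ex in examples], dtype=float)
    y = np.array([1 if ex.label == HE else 0 for ex in examples])
    return X, y, names


def train_svm(
    examples: Sequence[LabeledExample],
    kernel: str = "rbf",
    c: float = 1.0,
    gamma: float | str = "auto",
    seed: int = 0,
) -> TrainedModel:
    """Fit an SVM on z-normalized features.

    The scaler's per-feature means and scales are stored inside the model,
    along with the feature-name order and library version, so inference can
    verify alignment and impute sentinel-flagged values consistently.
    """
    if not examples:
        raise DegenerateTrainingError("no training examples")
    X, y, names = _as_matrix(examples)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training set contains a single class")
    pipe = Pipeline(
        [
            ("scaler", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=c, gamma=gamma, random_state=seed)),
        ]
    )
    pipe.fit(X, y)
    return TrainedModel(
        pipeline=pipe, feature_names=names, kernel=kernel, c=c, gamma=gamma, seed=seed
    )


def predict(model: TrainedModel, features: FeatureVector) -> str:
    """Classify one feature vector; names must match the training order."""
    if features.names != model.feature_names:
        raise ShapeError(
            "feature names/order do not match the trained model; refusing to "
            "predict on silently misaligned inputs"
        )
    X = features.as_array()[None, :]
    yhat = model.pipeline.predict(X)[0]
    return HE if yhat == 1 else NON_HE


def predict_many(model: TrainedModel, examples: Sequence[LabeledExample]) -> list[str]:
    X, _, names = _as_matrix(examples)
    if names != model.feature_names:
        raise ShapeError("feature names/order do not match the trained model")
    yhat = model.pipeline.predict(X)
    return [HE if v == 1 else NON_HE for v in yhat]


def evaluate(predictions: Sequence[str], truth: Sequence[str]) -> EvalCounts:
    """2x2 confusion counts with SE/SP in percent (HE is positive)."""
    if len(predictions) != len(truth):
        raise ShapeError("prediction and truth lengths differ")
    if len(predictions) == 0:
        raise EmptyEvalError("nothing to evaluate")
    tp = sum(1 for p, t in zip(predictions, truth) if p == HE and t == HE)
    tn = sum(1 for p, t in zip(predictions, truth) if p == NON_HE and t == NON_HE)
    fp = sum(1 for p, t in zip(predictions, truth) if p == HE and t == NON_HE)
    fn = sum(1 for p, t in zip(predictions, truth) if p == NON_HE and t == HE)
    return EvalCounts(tp=tp, tn=tn, fp=fp, fn=fn)


# ------------------------------------------------------------ experiment

_GRID_C = (0.1, 1.0, 10.0, 100.0)
_GRID_GAMMA = ("auto", 0.01, 0.1)


def candidates_for_sample(
    sample: SynthSample,
    preprocess_params: PreprocessParams = PreprocessParams(),
    filter_params: MatchedFilterParams = MatchedFilterParams(),
    opening_radius: int = 4,
    min_area: int = 5,
    margin: int = 80,
    iou_min: float = 0.2,
    sigmas: tuple[float, ...] = (6.0, 12.0),
    seed_pad: int = 12,
) -> list[LabeledExample]:
    """Full pipeline on one synthetic sample, returning labeled examples.

    Seed extraction runs on the calibrated image: with the background and
    border ring saturated white, rim lesions present the full dark-blob
    profile the matched filter is tuned to.
    """
    enhanced = preprocess_image(sample.image, preprocess_params)
    raw_green = green_channel(sample.image)
    products = calibrate(enhanced, green_raw=raw_green, margin=margin)
    seeds = extract_seed_points(
        products.calibrated_image, filter_params,
        opening_radius=opening_radius, min_area=min_area, sigmas=sigmas,
    )
    objects = segment_all(products.calibrated_image, seeds, products.search_space,
                          seed_pad=seed_pad)
    labels = annotate_candidates(objects, sample.hemorrhage_mask, iou_min=iou_min)
    examples = []
    for i, (obj, lab) in enumerate(zip(objects, labels)):
        fv = feat_mod.extract_conventional(obj, sample.image)
        examples.append(LabeledExample(features=fv, label=lab, object_id=i))
    return examples


def _score(counts: EvalCounts) -> float:
    se = counts.sensitivity
    sp = counts.specificity
    return np.nan_to_num(se) + np.nan_to_num(sp)


def run_experiment(
    samples: Sequence[SynthSample],
    feature_set: str = "conventional",
    split: tuple[float, float, float] = (0.5, 0.2, 0.3),
    seed: int = 0,
    shuffle_labels: bool = False,
    per_image: Sequence[list[LabeledExample]] | None = None,
    **pipeline_kwargs,
) -> tuple[EvalCounts, dict]:
    """Image-level split -> pipeline -> SVM model selection -> test counts.

    Each image is processed end to end (preprocess, seeds, calibration,
    SWAT, features, annotation); images are shuffled with ``seed`` and split
    into train/val/test by the given fractions, so no window leaks across
    splits.  C and gamma are chosen on the validation split by SE+SP; the
    selected model's test-split counts are returned with a report dict.
    ``shuffle_labels`` permutes training+validation labels as a chance
    control.  ``per_image`` optionally supplies already-extracted labeled
    examples per image (one list per sample, e.g. from
    :func:`candidates_for_sample`) so repeated experiments on the same
    images skip the pipeline stages.
    """
    if feature_set != "conventional":
        feat_mod.get_extractor(feature_set)  # raises CapabilityError if absent
    if abs(sum(split) - 1.0) > 1e-6:
        raise ValueError("split fractions must sum to 1")
    n = len(samples) if per_image is None else len(per_image)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = max(int(round(split[0] * n)), 2)
    n_val = max(int(round(split[1] * n)), 2)
    if n_train + n_val + 2 > n:
        raise ValueError("need at least 2 images per split")
    idx_train = order[:n_train]
    idx_val = order[n_train : n_train + n_val]
    idx_test = order[n_train + n_val :]

    if per_image is None:
        per_image = [candidates_for_sample(s, **pipeline_kwargs) for s in samples]
    train = [ex for i in idx_train for ex in per_image[i]]
    val = [ex for i in idx_val for ex in per_image[i]]
    test = [ex for i in idx_test for ex in per_image[i]]
    for name, part in (("train", train), ("val", val), ("test", test)):
        if not part:
            raise HemsegError(f"no candidate windows in the {name} split")

    if shuffle_labels:
        perm_labels = [ex.label for ex in train + val]
        rng.shuffle(perm_labels)
        relabeled = [
            LabeledExample(features=ex.features, label=lab, object_id=ex.object_id)
            for ex, lab in zip(train + val, perm_labels)
        ]
        train = relabeled[: len(train)]
        val = relabeled[len(train) :]

    best = None
    for c in _GRID_C:
        for gamma in _GRID_GAMMA:
            try:
                model = train_svm(train, kernel="rbf", c=c, gamma=gamma, seed=seed)
            except DegenerateTrainingError:
                raise
            counts = evaluate(predict_many(model, val), [ex.label for ex in val])
            key = (_score(counts), -c)
            if best is None or key > best[0]:
                best = (key, model, (c, gamma))
    assert best is not None
    _, model, (c_sel, g_sel) = best
    test_counts = evaluate(predict_many(model, test), [ex.label for ex in test])
    report = {
        "n_images": n,
        "split_images": {
            "train": [int(i) for i in idx_train],
            "val": [int(i) for i in idx_val],
            "test": [int(i) for i in idx_test],
        },
        "n_windows": {"train": len(train), "val": len(val), "test": len(test)},
        "selected": {"C": c_sel, "gamma": g_sel, "kernel": "rbf"},
        "feature_set": feature_set,
        "test": test_counts.as_dict(),
    }
    return test_counts, report
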