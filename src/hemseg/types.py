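"""Shared domain types for the hemorrhage-detection pipeline.

Coordinate convention used throughout: images are indexed ``[row, col]``,
0-based.  A :class:`BoundingBox` stores inclusive edges as the vertex vector
``V = (v1, v2, v3, v4)`` = (left column, top row, right column, bottom row),
so the crop of image ``I`` is ``I[v2:v4+1, v1:v3+1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class HemsegError(Exception):
    """Base class for pipeline errors."""


class ShapeError(HemsegError):
    """Input raster has the wrong dimensionality or mismatched shapes."""


class DegenerateHistogramError(HemsegError):
    """Histogram has too little structure for the requested operation."""


class InfeasibleSplitError(DegenerateHistogramError):
    """Fewer occupied gray levels than requested regions."""


class ZeroVarianceError(DegenerateHistogramError):
    """Single occupied gray level: total variance is zero."""


class NoFovError(HemsegError):
    """No retinal field of view found after masking."""


class DegenerateRingError(HemsegError):
    """Erosion annihilated the retinal mask; no border ring exists."""


class PlacementError(HemsegError):
    """Synthetic lesion/vessel placement could not satisfy the constraints."""


class EmptyObjectError(HemsegError):
    """Feature extraction requested on an empty mask."""


class CapabilityError(HemsegError):
    """An optional capability (e.g. a deep-feature backend) is unavailable."""


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive window vertices ``V = (v1, v2, v3, v4)``.

    v1/v3 are the left/right columns, v2/v4 the top/bottom rows.
    """

    v1: int
    v2: int
    v3: int
    v4: int

    def __post_init__(self) -> None:
        if self.v1 > self.v3 or self.v2 > self.v4:
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.v4 - self.v2 + 1

    @property
    def width(self) -> int:
        return self.v3 - self.v1 + 1

    @property
    def center(self) -> tuple[float, float]:
        """(row, col) of the geometric window center."""
        return ((self.v2 + self.v4) / 2.0, (self.v1 + self.v3) / 2.0)

    def contains(self, row: float, col: float) -> bool:
        return self.v2 <= row <= self.v4 and self.v1 <= col <= self.v3

    def crop(self, image: np.ndarray) -> np.ndarray:
        return image[self.v2 : self.v4 + 1, self.v1 : self.v3 + 1]

    def clipped(self, shape: tuple[int, int]) -> "BoundingBox":
        h, w = shape[:2]
        return BoundingBox(
            max(self.v1, 0), max(self.v2, 0), min(self.v3, w - 1), min(self.v4, h - 1)
        )


@dataclass(frozen=True)
class SeedPoint:
    """A prospective hemorrhage location from the matched-filter stage."""

    bbox: BoundingBox
    centroid: tuple[float, float]  # (row, col)
    area: int

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("seed area must be >= 1")
        if not self.bbox.contains(*self.centroid):
            raise ValueError("centroid outside bounding box")


@dataclass(frozen=True)
class ThresholdSolution:
    """Optimal multi-region threshold set for one window histogram.

    ``eta`` is the effectiveness ratio sigma_B^2 / sigma_T^2: the fraction of
    the window's intensity variance explained by splitting it into
    ``n_regions`` gray-level strata at ``thresholds``.
    """

    n_regions: int
    thresholds: tuple[int, ...]
    tau_star: int
    eta: float
    between_var: float
    total_var: float
    region_weights: tuple[float, ...]
    region_means: tuple[float, ...]
    image_mean: float
    n_gray_levels: int

    def __post_init__(self) -> None:
        if len(self.thresholds) != self.n_regions - 1:
            raise ValueError("need n_regions - 1 thresholds")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def min_threshold(self) -> int:
        return self.thresholds[0]


@dataclass
class SegmentationWindow:
    """One smart-window state: crop W1, its binarization W2, border flags Q."""

    bbox: BoundingBox
    pixels: np.ndarray  # W1, uint8 crop of the calibrated image
    binary: np.ndarray | None = None  # W2, bool
    border_flags: tuple[bool, bool, bool, bool] = (False, False, False, False)
    # Q = (q1 left, q2 top, q3 right, q4 bottom)

    @property
    def center(self) -> tuple[float, float]:
        """Window center in window-local (row, col) coordinates."""
        h, w = self.pixels.shape
        return ((h - 1) / 2.0, (w - 1) / 2.0)


@dataclass
class CandidateObject:
    """A segmented object mapped back to image-frame coordinates."""

    pixel_coords: np.ndarray  # (n, 2) int array of (row, col), image frame
    area: int
    center_distance: float
    source_seed: int
    final_bbox: BoundingBox
    mask: np.ndarray  # bool, image frame
    converged: bool = True

    def __post_init__(self) -> None:
        if self.center_distance < 0:
            raise ValueError("center_distance must be >= 0")
        if self.area != len(self.pixel_coords):
            raise ValueError("area must equal |pixel_coords|")


@dataclass(frozen=True)
class EvalCounts:
    """2x2 confusion counts with sensitivity/specificity in percent."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        """SE = 100 * TP / (TP + FN); NaN when no positives exist."""
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom > 0 else float("nan")

    @property
    def specificity(self) -> float:
        """SP = 100 * TN / (TN + FP); NaN when no negatives exist."""
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom > 0 else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered real-valued features for one candidate object."""

    values: tuple[float, ...]
    names: tuple[str, ...]
    object_id: int = -1

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must align")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def as_gray_u8(image: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate a single-channel 8-bit image and return it as uint8."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ShapeError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ShapeError(f"{name} is empty")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr


def as_rgb_u8(image: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate an RGB 8-bit image."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"{name} must be HxWx3 RGB, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr
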