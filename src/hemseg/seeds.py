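"""Prospective hemorrhage locations (seed points).

Hemorrhages are dark blobs surrounded by brighter retina, so an *inverted*
Gaussian matched filter — low at the center, rising toward the rim — gives
a high correlation response at their centers (and along vessels, which share
the dark intensity profile).  The response is thresholded by a cross-entropy
criterion computed from the quadrants of its gray-level co-occurrence matrix
(GLCM), and a morphological opening then breaks the thin vasculature, leaving
compact blob cores whose connected components become seed points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.feature import graycomatrix
from skimage.measure import label, regionprops

from .types import (
    BoundingBox,
    DegenerateHistogramError,
    SeedPoint,
    ShapeError,
    as_gray_u8,
)

__all__ = [
    "MatchedFilterParams",
    "matched_filter_response",
    "glcm_cross_entropy_threshold",
    "break_vasculature",
    "extract_seed_points",
]


@dataclass(frozen=True)
class MatchedFilterParams:
    """Inverted-Gaussian kernel parameters.

    ``sigma`` sets the blob scale the filter responds to; the kernel spans
    ``2*kernel_radius + 1`` pixels per side.  With ``zero_mean`` the kernel
    is shifted to zero sum so flat regions yield exactly zero response.
    """

    sigma: float = 8.0
    kernel_radius: int = 16
    zero_mean: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.kernel_radius < 2 * self.sigma:
            raise ValueError("kernel_radius must be >= 2*sigma")


def matched_filter_kernel(params: MatchedFilterParams) -> np.ndarray:
    """Isotropic inverted-Gaussian template 1 - exp(-r^2 / 2 sigma^2)."""
    r = params.kernel_radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = 1.0 - np.exp(-(yy**2 + xx**2) / (2.0 * params.sigma**2))
    if params.zero_mean:
        k = k - k.mean()
    return k


def matched_filter_response(
    image: np.ndarray, params: MatchedFilterParams = MatchedFilterParams()
) -> np.ndarray:
    """Correlate the image with the inverted-Gaussian kernel.

    The response is maximal at the centers of dark blobs of scale ~sigma on
    a bright surround.  Returned as float64 in arbitrary units.
    """
    img = as_gray_u8(image).astype(float)
    k = matched_filter_kernel(params)
    if k.shape[0] > img.shape[0] or k.shape[1] > img.shape[1]:
        raise ShapeError(
            f"kernel {k.shape} larger than image {img.shape}"
        )
    return ndi.correlate(img, k, mode="reflect")


def _glcm_probabilities(quantized: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric, normalized GLCM from horizontal + vertical unit offsets."""
    glcm = graycomatrix(
        quantized,
        distances=[1],
        angles=[0.0, np.pi / 2],
        levels=levels,
        symmetric=True,
        normed=False,
    ).astype(float)
    p = glcm[:, :, 0, :].sum(axis=-1)
    total = p.sum()
    if total == 0:
        raise DegenerateHistogramError("image too small for co-occurrence pairs")
    return p / total


def quadrant_entropy_objective(p: np.ndarray, t: int) -> float:
    """Default thresholding objective on the GLCM quadrants induced by t.

    The background-background block holds co-occurrences with both levels
    <= t, the foreground-foreground block those with both levels > t.
    Each block's probabilities are renormalized and its Shannon entropy
    computed; the objective is the *negative* sum of the two block
    entropies, so minimizing it maximizes the second-order entropy of the
    two homogeneous blocks (the classic co-occurrence entropy criterion
    used for matched-filter response maps).  Mixed (off-quadrant) pairs
    contribute nothing.
    """
    L = p.shape[0]
    out = 0.0
    for sl in ((slice(0, t + 1), slice(0, t + 1)),
               (slice(t + 1, L), slice(t + 1, L))):
        blk = p[sl]
        mass = blk.sum()
        if mass <= 0:
            continue
        pn = blk[blk > 0] / mass
        out -= float(-(pn * np.log(pn)).sum())
    return out


def glcm_cross_entropy_threshold(
    image: np.ndarray,
    levels: int = 256,
    objective: Callable[[np.ndarray, int], float] | None = None,
) -> float:
    """Threshold a real-valued image by GLCM quadrant entropy.

    The image is rescaled to ``levels`` gray levels, the co-occurrence
    matrix built, and the threshold minimizing the objective found by a
    successive scan from darkest to brightest (first minimum kept).  The
    objective is swappable; the default is
    :func:`quadrant_entropy_objective`.  The returned threshold is mapped
    back to the input image's own gray scale, so callers can binarize the
    original image directly with ``image > t_star``.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ShapeError("threshold input must be a non-empty 2-D image")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateHistogramError("single gray level: nothing to threshold")
    q = np.clip(((arr - lo) / (hi - lo) * (levels - 1)).round(), 0, levels - 1)
    q = q.astype(np.uint16 if levels > 256 else np.uint8)
    p = _glcm_probabilities(q, levels)
    obj = objective or quadrant_entropy_objective
    occupied = np.nonzero(p.sum(axis=0) + p.sum(axis=1))[0]
    if occupied.size < 2:
        raise DegenerateHistogramError("single occupied co-occurrence level")
    best_t, best_val = None, np.inf
    for t in range(int(occupied[0]), int(occupied[-1])):
        val = obj(p, t)
        if val < best_val:
            best_val, best_t = val, t
    assert best_t is not None
    return lo + best_t * (hi - lo) / (levels - 1)


def quantize_response(response: np.ndarray, levels: int = 256) -> np.ndarray:
    """Rescale a real response image to 0..levels-1 integers."""
    arr = np.asarray(response, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    q = np.clip(((arr - lo) / (hi - lo) * (levels - 1)).round(), 0, levels - 1)
    return q.astype(np.uint16 if levels > 256 else np.uint8)


def break_vasculature(mask: np.ndarray, opening_radius: int = 4) -> np.ndarray:
    """Morphological opening with a disc: removes thin vessel-like strands.

    Structures narrower than ~2*radius disappear; compact blob cores are
    retained.  Idempotent, and the output is always a subset of the input.
    """
    m = np.asarray(mask, dtype=bool)
    if opening_radius <= 0:
        return m.copy()
    return morphology.opening(m, morphology.disk(opening_radius))


def extract_seed_points(
    image: np.ndarray,
    params: MatchedFilterParams = MatchedFilterParams(),
    opening_radius: int = 4,
    min_area: int = 5,
    levels: int = 256,
    sigmas: Sequence[float] | None = None,
) -> list[SeedPoint]:
    """Matched filter -> GLCM threshold -> opening -> connected components.

    ``sigmas`` optionally runs the filter at several scales (off by
    default); each scale is thresholded and opened independently and the
    per-scale seed lists concatenated, so a fine-scale core keeps its own
    tight bounding box even when a coarse scale merges it with neighboring
    structures.  Components are 8-connected; those with area < ``min_area``
    are dropped, as are seeds duplicating an earlier scale's bounding box.
    """
    img = as_gray_u8(image)
    scale_list = list(sigmas) if sigmas else [params.sigma]
    seeds: list[SeedPoint] = []
    seen_boxes: set[tuple[int, int, int, int]] = set()
    for s in scale_list:
        p = MatchedFilterParams(
            sigma=s, kernel_radius=max(params.kernel_radius, int(np.ceil(2 * s))),
            zero_mean=params.zero_mean,
        )
        resp = matched_filter_response(img, p)
        t_star = glcm_cross_entropy_threshold(resp, levels)
        opened = break_vasculature(resp > t_star, opening_radius)
        lab = label(opened, connectivity=2)
        for rp in regionprops(lab):
            if rp.area < min_area:
                continue
            r0, c0, r1, c1 = rp.bbox  # half-open
            key = (c0, r0, c1 - 1, r1 - 1)
            if key in seen_boxes:
                continue
            seen_boxes.add(key)
            seeds.append(
                SeedPoint(
                    bbox=BoundingBox(v1=c0, v2=r0, v3=c1 - 1, v4=r1 - 1),
                    centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                    area=int(rp.area),
                )
            )
    return seeds
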