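"""Feature extraction for candidate objects.

Five conventional blocks, each aimed at one confusable structure class:

- shape (connected-component) features separate line-like vessels from
  roughly circular hemorrhages;
- edge (Laplacian/Sobel boundary) features separate sharp-edged hemorrhages
  from the soft-edged macula;
- texture (masked GLCM) features capture the smooth, homogeneous interior
  of hemorrhages;
- color features separate true (reddish) lesions from gray illumination
  shades of equal darkness;
- hand-crafted contour features (closedness, corner count, corner-to-center
  distances) capture boundary regularity.

A pluggable :class:`FeatureExtractor` interface admits deep-feature
backends (e.g. CNN hidden-layer activations); none ships with the core
package, and requesting an unregistered one raises a capability error.
"""

from __future__ import annotations

from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.color import rgb2hsv
from skimage.feature import graycoprops
from skimage.measure import find_contours, regionprops

from .types import (
    CandidateObject,
    CapabilityError,
    EmptyObjectError,
    FeatureVector,
    HemsegError,
    ShapeError,
    as_gray_u8,
    as_rgb_u8,
)

__all__ = [
    "shape_features",
    "edge_features",
    "texture_features",
    "color_features",
    "handcrafted_features",
    "extract_conventional",
    "deep_features",
    "FeatureExtractor",
    "register_extractor",
    "get_extractor",
    "CONVENTIONAL_FEATURE_NAMES",
]


class TooFewPixelsError(HemsegError):
    """Masked region too small for the requested texture statistics."""


# ---------------------------------------------------------------- shape


def _local_mask(obj_mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(obj_mask, dtype=bool)
    if not mask.any():
        raise EmptyObjectError("empty object mask")
    return mask


def shape_features(obj: CandidateObject | np.ndarray) -> FeatureVector:
    """Connected-component descriptors of the object mask.

    Circularity is 4*pi*A/P^2 (1 for an ideal disc); the axis ratio is
    major/minor axis length of the fitted ellipse.  Degenerate regions use
    a perimeter floor of 1 so every output stays finite.
    """
    mask = _local_mask(obj.mask if isinstance(obj, CandidateObject) else obj)
    rp = regionprops(mask.astype(np.uint8))[0]
    area = float(rp.area)
    perimeter = max(float(rp.perimeter), 1.0)
    circularity = 4.0 * np.pi * area / perimeter**2
    minor = max(float(rp.axis_minor_length), 1.0)
    major = max(float(rp.axis_major_length), minor)
    values = (
        area,
        perimeter,
        circularity,
        float(rp.eccentricity),
        float(rp.solidity),
        float(rp.extent),
        major / minor,
    )
    names = ("area", "perimeter", "circularity", "eccentricity",
             "solidity", "extent", "axis_ratio")
    return FeatureVector(values=values, names=names)


# ----------------------------------------------------------------- edge


def edge_features(patch: np.ndarray, mask: np.ndarray) -> FeatureVector:
    """Laplacian and Sobel gradient statistics on the object boundary ring."""
    m = _local_mask(mask)
    p = np.asarray(patch, dtype=float)
    if p.shape != m.shape:
        raise ShapeError("patch and mask shapes differ")
    boundary = m & ~ndi.binary_erosion(m)
    if not boundary.any():
        boundary = m
    lap = np.abs(ndi.laplace(p))
    gx, gy = ndi.sobel(p, axis=1), ndi.sobel(p, axis=0)
    grad = np.hypot(gx, gy)
    values = (
        float(lap[boundary].mean()),
        float(lap[boundary].max()),
        float(grad[boundary].mean()),
        float(grad[boundary].max()),
    )
    names = ("laplacian_mean", "laplacian_max", "gradient_mean", "gradient_max")
    return FeatureVector(values=values, names=names)


# -------------------------------------------------------------- texture

_GLCM_LEVELS = 32


def _masked_glcm(patch: np.ndarray, mask: np.ndarray, levels: int = _GLCM_LEVELS) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix restricted to masked pairs."""
    q = (as_gray_u8(patch).astype(int) * levels) // 256
    glcm = np.zeros((levels, levels), dtype=float)
    for dr, dc in ((0, 1), (1, 0)):
        a = mask[: mask.shape[0] - dr, : mask.shape[1] - dc]
        b = mask[dr:, dc:]
        both = a & b
        qi = q[: q.shape[0] - dr, : q.shape[1] - dc][both]
        qj = q[dr:, dc:][both]
        np.add.at(glcm, (qi, qj), 1.0)
        np.add.at(glcm, (qj, qi), 1.0)  # symmetric
    total = glcm.sum()
    if total == 0:
        raise TooFewPixelsError("no co-occurring masked pixel pairs")
    return glcm / total


def texture_features(patch: np.ndarray, mask: np.ndarray, min_pixels: int = 16) -> FeatureVector:
    """Masked GLCM texture statistics plus intensity variance and entropy."""
    m = _local_mask(mask)
    p = as_gray_u8(patch)
    if p.shape != m.shape:
        raise ShapeError("patch and mask shapes differ")
    if int(m.sum()) < min_pixels:
        raise TooFewPixelsError(f"need >= {min_pixels} masked pixels, got {int(m.sum())}")
    glcm = _masked_glcm(p, m)[:, :, None, None]
    contrast = float(graycoprops(glcm, "contrast")[0, 0])
    correlation = float(graycoprops(glcm, "correlation")[0, 0])
    energy = float(graycoprops(glcm, "energy")[0, 0])
    homogeneity = float(graycoprops(glcm, "homogeneity")[0, 0])
    vals = p[m].astype(float)
    variance = float(vals.var())
    hist = np.bincount(p[m], minlength=256).astype(float)
    prob = hist[hist > 0] / hist.sum()
    entropy = float(-(prob * np.log2(prob)).sum())
    values = (contrast, correlation, energy, homogeneity, variance, entropy)
    names = ("glcm_contrast", "glcm_correlation", "glcm_energy",
             "glcm_homogeneity", "intensity_variance", "intensity_entropy")
    return FeatureVector(values=values, names=names)


# ---------------------------------------------------------------- color

_SURROUND_RADIUS = 5
_RATIO_EPS = 1.0


def color_features(rgb_patch: np.ndarray, mask: np.ndarray) -> FeatureVector:
    """Color statistics of the object and its contrast against the surround.

    The surround is a 5-px dilation ring around the object inside the
    patch.  When the ring is empty (object fills the patch to its edges),
    the ratio features carry a 0 sentinel and ``surround_missing`` is 1.
    """
    rgb = as_rgb_u8(rgb_patch).astype(float)
    m = _local_mask(mask)
    if rgb.shape[:2] != m.shape:
        raise ShapeError("patch and mask shapes differ")
    hsv = rgb2hsv(rgb / 255.0)
    means = [float(rgb[..., c][m].mean()) for c in range(3)]
    stds = [float(rgb[..., c][m].std()) for c in range(3)]
    hsv_means = [float(hsv[..., c][m].mean()) for c in range(3)]
    surround = morphology.dilation(m, morphology.disk(_SURROUND_RADIUS)) & ~m
    if surround.any():
        ratios = [
            (means[c] + _RATIO_EPS) / (float(rgb[..., c][surround].mean()) + _RATIO_EPS)
            for c in range(3)
        ]
        missing = 0.0
    else:
        ratios = [0.0, 0.0, 0.0]
        missing = 1.0
    values = (*means, *stds, *hsv_means, *ratios, missing)
    names = ("r_mean", "g_mean", "b_mean", "r_std", "g_std", "b_std",
             "hue_mean", "saturation_mean", "value_mean",
             "r_ratio", "g_ratio", "b_ratio", "surround_missing")
    return FeatureVector(values=values, names=names)


# ---------------------------------------------------------- hand-crafted

_CORNER_ANGLE_THRESHOLD = 0.9  # radians of turning over the probe span


def _trace_contour(mask: np.ndarray) -> np.ndarray | None:
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    longest = max(contours, key=len)
    return longest - 1.0  # undo padding offset


def _corner_indices(contour: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Curvature maxima along a closed contour.

    Turning angle is measured between the chords k points behind and ahead
    of each sample; peaks above the angle threshold with non-maximum
    suppression over the probe span count as corners.
    """
    n = len(contour)
    k = max(3, n // 16)
    prev = np.roll(contour, k, axis=0)
    nxt = np.roll(contour, -k, axis=0)
    v1 = contour - prev
    v2 = nxt - contour
    dot = (v1 * v2).sum(axis=1)
    norm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    ang = np.arccos(np.clip(dot / np.maximum(norm, 1e-12), -1.0, 1.0))
    corners = []
    order = np.argsort(-ang)
    taken = np.zeros(n, dtype=bool)
    for i in order:
        if ang[i] < _CORNER_ANGLE_THRESHOLD:
            break
        if taken[i]:
            continue
        corners.append(i)
        lo = np.arange(i - k, i + k + 1) % n
        taken[lo] = True
    idx = np.array(sorted(corners), dtype=int)
    return idx, ang


def handcrafted_features(obj: CandidateObject | np.ndarray,
                         patch: np.ndarray | None = None) -> FeatureVector:
    """Contour closedness, corner count, and corner-to-center spread."""
    mask = _local_mask(obj.mask if isinstance(obj, CandidateObject) else obj)
    touches_edge = (
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    closed = 0.0 if touches_edge else 1.0
    contour = _trace_contour(mask)
    if contour is None or len(contour) < 8:
        values = (closed, 0.0, 0.0, 0.0)
    else:
        idx, _ = _corner_indices(contour)
        centroid = np.argwhere(mask).mean(axis=0)
        if idx.size:
            d = np.linalg.norm(contour[idx] - centroid, axis=1)
            values = (closed, float(idx.size), float(d.mean()), float(d.std()))
        else:
            values = (closed, 0.0, 0.0, 0.0)
    names = ("contour_closed", "n_corners", "corner_dist_mean", "corner_dist_std")
    return FeatureVector(values=values, names=names)


# ----------------------------------------------------- conventional set

_BLOCKS = ("shape", "edge", "texture", "color", "handcrafted")
_BLOCK_NAMES = {
    "shape": ("area", "perimeter", "circularity", "eccentricity",
              "solidity", "extent", "axis_ratio"),
    "edge": ("laplacian_mean", "laplacian_max", "gradient_mean", "gradient_max"),
    "texture": ("glcm_contrast", "glcm_correlation", "glcm_energy",
                "glcm_homogeneity", "intensity_variance", "intensity_entropy"),
    "color": ("r_mean", "g_mean", "b_mean", "r_std", "g_std", "b_std",
              "hue_mean", "saturation_mean", "value_mean",
              "r_ratio", "g_ratio", "b_ratio", "surround_missing"),
    "handcrafted": ("contour_closed", "n_corners", "corner_dist_mean",
                    "corner_dist_std"),
}

CONVENTIONAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{block}.{name}" for block in _BLOCKS for name in _BLOCK_NAMES[block]
) + tuple(f"{block}.missing" for block in _BLOCKS)

_PATCH_PAD = 8


def _object_patches(
    obj: CandidateObject, image: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local RGB patch, green patch and mask around the object bbox."""
    rgb = as_rgb_u8(image)
    rows, cols = np.nonzero(obj.mask)
    r0 = max(int(rows.min()) - _PATCH_PAD, 0)
    r1 = min(int(rows.max()) + _PATCH_PAD + 1, rgb.shape[0])
    c0 = max(int(cols.min()) - _PATCH_PAD, 0)
    c1 = min(int(cols.max()) + _PATCH_PAD + 1, rgb.shape[1])
    rgb_patch = rgb[r0:r1, c0:c1]
    mask_patch = obj.mask[r0:r1, c0:c1]
    return rgb_patch, rgb_patch[:, :, 1], mask_patch


def extract_conventional(obj: CandidateObject, image: np.ndarray) -> FeatureVector:
    """All five conventional blocks in a fixed, documented order.

    Blocks that fail on a degenerate region (e.g. too few pixels for
    texture) are filled with a 0 sentinel and their ``<block>.missing``
    indicator set to 1; downstream training imputes them from training-set
    means.
    """
    rgb_patch, gray_patch, mask_patch = _object_patches(obj, image)
    block_fns: dict[str, Callable[[], FeatureVector]] = {
        "shape": lambda: shape_features(mask_patch),
        "edge": lambda: edge_features(gray_patch, mask_patch),
        "texture": lambda: texture_features(gray_patch, mask_patch),
        "color": lambda: color_features(rgb_patch, mask_patch),
        "handcrafted": lambda: handcrafted_features(mask_patch),
    }
    values: list[float] = []
    missing: list[float] = []
    for block in _BLOCKS:
        n = len(_BLOCK_NAMES[block])
        try:
            fv = block_fns[block]()
            if len(fv.values) != n:
                raise HemsegError(f"block {block} returned wrong arity")
            values.extend(fv.values)
            missing.append(0.0)
        except HemsegError:
            values.extend([0.0] * n)
            missing.append(1.0)
    values.extend(missing)
    return FeatureVector(
        values=tuple(values), names=CONVENTIONAL_FEATURE_NAMES,
        object_id=obj.source_seed,
    )


# ------------------------------------------------------- deep interface


@runtime_checkable
class FeatureExtractor(Protocol):
    """Deterministic patch-to-vector feature backend."""

    name: str
    output_dim: int
    input_size: tuple[int, int]

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


_EXTRACTOR_REGISTRY: dict[str, Callable[[], FeatureExtractor]] = {}


def register_extractor(name: str, factory: Callable[[], FeatureExtractor]) -> None:
    """Register a deep-feature backend factory under ``name``."""
    _EXTRACTOR_REGISTRY[name] = factory


def get_extractor(name: str) -> FeatureExtractor:
    if name not in _EXTRACTOR_REGISTRY:
        raise CapabilityError(
            f"no feature extractor named {name!r} is registered; deep backends "
            f"require the optional torch/torchvision adapter — install it and "
            f"register the extractor via hemseg.features.register_extractor"
        )
    return _EXTRACTOR_REGISTRY[name]()


def deep_features(patch: np.ndarray, extractor: FeatureExtractor) -> FeatureVector:
    """Hidden-layer activation vector from a registered deep backend.

    The patch is resized to the extractor's input size; spatial activation
    maps are global-average-pooled to a vector.
    """
    from skimage.transform import resize

    rgb = as_rgb_u8(patch).astype(float) / 255.0
    resized = resize(rgb, extractor.input_size, anti_aliasing=True)
    act = np.asarray(extractor(resized), dtype=float)
    if act.ndim > 1:
        act = act.reshape(act.shape[0], -1).mean(axis=1)
    if act.size != extractor.output_dim:
        raise HemsegError(
            f"extractor {extractor.name} returned {act.size} values, "
            f"declared {extractor.output_dim}"
        )
    names = tuple(f"{extractor.name}.{i}" for i in range(act.size))
    return FeatureVector(values=tuple(float(v) for v in act), names=names)
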