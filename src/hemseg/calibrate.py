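"""Image calibration: illuminate the background and mark the retinal border.

Hemorrhages at the retinal rim blend into the near-black frame outside the
field of view (FOV), which is darker than any lesion and would swallow a
threshold-based segmentation.  Calibration therefore (a) estimates the FOV
disc (the *retinal mask*) from a median-filtered green channel, (b) marks a
thin border ring just inside it, and (c) saturates both the outside and the
ring to white in the enhanced green channel, so rim lesions become dark
objects on a bright surround like any interior lesion.  A *search space* —
the retinal mask dilated by a margin — bounds all window growth during
segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .types import DegenerateRingError, NoFovError, ShapeError, as_gray_u8

__all__ = [
    "CalibrationProducts",
    "compute_retinal_mask",
    "compute_border",
    "calibrate_image",
    "compute_search_space",
    "calibrate",
]


@dataclass
class CalibrationProducts:
    retinal_mask: np.ndarray  # bool, FOV disc
    retinal_border: np.ndarray  # bool ring inside the mask
    calibrated_image: np.ndarray  # uint8
    search_space: np.ndarray  # bool, mask dilated by the margin


def compute_retinal_mask(
    green: np.ndarray,
    median_radius: int = 15,
    mask_threshold: int | None = None,
    convexify: bool = True,
) -> np.ndarray:
    """Estimate the FOV disc from the (enhanced or raw) green channel.

    Median filtering suppresses background variation; the result is
    binarized (Otsu by default), the largest bright component kept and its
    holes filled.  Because the camera field of view is convex, the mask is
    then convexified, so dark lesions sitting on the FOV boundary do not
    carve notches out of it (a notch there would white such lesions out of
    the calibrated image).
    """
    img = as_gray_u8(green)
    med = ndi.median_filter(img, footprint=morphology.disk(median_radius))
    if mask_threshold is None:
        if med.min() == med.max():
            # flat image: all-bright is a full-frame FOV, all-dark has none
            if med.min() < 10:
                raise NoFovError("no bright retinal region found")
            return np.ones(img.shape, dtype=bool)
        thr = filters.threshold_otsu(med)
    else:
        thr = mask_threshold
    binary = med > thr
    if not binary.any():
        raise NoFovError("no bright retinal region found after thresholding")
    lab, n = ndi.label(binary)
    largest = np.argmax(ndi.sum_labels(np.ones_like(lab), lab, range(1, n + 1))) + 1
    mask = lab == largest
    mask = ndi.binary_fill_holes(mask)
    if convexify:
        mask = morphology.convex_hull_image(mask)
    return mask


def compute_border(retinal_mask: np.ndarray, erosion_radius: int = 3) -> np.ndarray:
    """Ring = mask minus its erosion by a disc of ``erosion_radius``."""
    mask = np.asarray(retinal_mask, dtype=bool)
    if erosion_radius <= 0:
        return np.zeros(mask.shape, dtype=bool)
    # zero border value so a mask touching the frame erodes at the frame too
    eroded = ndi.binary_erosion(
        mask, structure=morphology.disk(erosion_radius), border_value=0
    )
    if mask.any() and not eroded.any():
        raise DegenerateRingError("erosion annihilated the retinal mask")
    return mask & ~eroded


def calibrate_image(
    green: np.ndarray, retinal_mask: np.ndarray, border: np.ndarray
) -> np.ndarray:
    """Saturate the non-retinal background and the border ring to white.

    Output = green + 255*(NOT mask) + 255*border, clipped to [0, 255]:
    interior pixels keep their enhanced green value, everything outside the
    mask and on the ring becomes bright.
    """
    img = as_gray_u8(green)
    mask = np.asarray(retinal_mask, dtype=bool)
    ring = np.asarray(border, dtype=bool)
    if mask.shape != img.shape or ring.shape != img.shape:
        raise ShapeError("mask shapes must match the image")
    out = img.astype(np.int32)
    out[~mask] += 255
    out[ring] += 255
    return np.clip(out, 0, 255).astype(np.uint8)


def compute_search_space(retinal_mask: np.ndarray, margin: int = 80) -> np.ndarray:
    """Dilate the retinal mask by ``margin`` pixels (Euclidean), frame-clipped.

    Provides room for segmentation windows around lesions at the retinal
    border.  Implemented via the distance transform of the complement, which
    is exact for a disc structuring element.
    """
    mask = np.asarray(retinal_mask, dtype=bool)
    if margin <= 0 or not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= margin


def calibrate(
    green_enhanced: np.ndarray,
    green_raw: np.ndarray | None = None,
    median_radius: int = 15,
    erosion_radius: int = 3,
    margin: int = 80,
) -> CalibrationProducts:
    """Full calibration from the enhanced green channel.

    The retinal mask is computed from ``green_raw`` when given (the raw
    channel has the cleanest background/FOV separation), otherwise from the
    enhanced channel.
    """
    src = green_raw if green_raw is not None else green_enhanced
    mask = compute_retinal_mask(src, median_radius=median_radius)
    ring = compute_border(mask, erosion_radius=erosion_radius)
    calibrated = calibrate_image(green_enhanced, mask, ring)
    space = compute_search_space(mask, margin=margin)
    return CalibrationProducts(
        retinal_mask=mask,
        retinal_border=ring,
        calibrated_image=calibrated,
        search_space=space,
    )
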