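"""Smart-window adaptive thresholding (SWAT) segmentation.

SWAT segments one dark object per seed point from the calibrated image.
For the current window it:

1. finds the optimal multi-region gray-level partition by maximizing the
   between-region variance  sigma_B^2 = sum_z omega_z (mu_z - mu_T)^2
   over strictly increasing threshold tuples (the multilevel extension of
   Otsu's criterion),
2. grows the number of regions R = 2, 3, ... until the effectiveness
   eta = sigma_B^2 / sigma_T^2 reaches 0.8 (or R caps at 20), so windows
   with richer intensity structure receive finer partitions,
3. keeps the darkest stratum (pixels <= min threshold) as foreground,
4. among the foreground components keeps the two largest and selects the
   one nearer the window center (seeds come from a matched filter tuned to
   hemorrhage centers, so centrality is evidence of lesion-ness),
5. inspects which window sides the selected object touches (flags
   Q = [q1 left, q2 top, q3 right, q4 bottom]) and grows the window
   directionally — left/top edges by 5 px, right/bottom edges by 10 px —
   but only while the moved edge stays inside the search space S,
6. repeats until the object touches no window side (Q = 0), every touched
   side is blocked by S, or an iteration cap is reached.

The search space (retinal mask dilated by a margin) keeps windows that
chase vessels or background shades from marching off the retina.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from skimage.measure import label

from .types import (
    BoundingBox,
    CandidateObject,
    InfeasibleSplitError,
    SeedPoint,
    SegmentationWindow,
    ThresholdSolution,
    ZeroVarianceError,
    as_gray_u8,
)

__all__ = [
    "multiregion_threshold",
    "adaptive_region_count",
    "binarize_window",
    "select_candidate",
    "grow_window",
    "segment_from_seed",
    "segment_all",
]

# window-edge growth amounts: (left, top) shrink coordinates by 5,
# (right, bottom) advance by 10
GROW_LEFT_TOP = 5
GROW_RIGHT_BOTTOM = 10

# exhaustive search is used while the tuple count stays below this
_EXHAUSTIVE_CAP = 120_000


def _histogram_moments(hist: np.ndarray) -> tuple[np.ndarray, float, float]:
    total = hist.sum()
    p = hist / total
    levels = np.arange(hist.size, dtype=float)
    mu_t = float((p * levels).sum())
    sigma_t2 = float((p * (levels - mu_t) ** 2).sum())
    return p, mu_t, sigma_t2


def _region_stats(
    p: np.ndarray, thresholds: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Weights and means of the regions induced by a threshold tuple."""
    levels = np.arange(p.size, dtype=float)
    bounds = [-1, *thresholds, p.size - 1]
    weights, means = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sl = slice(a + 1, b + 1)
        w = float(p[sl].sum())
        m = float((p[sl] * levels[sl]).sum() / w) if w > 0 else 0.0
        weights.append(w)
        means.append(m)
    return np.array(weights), np.array(means)


def _between_variance(weights: np.ndarray, means: np.ndarray, mu_t: float) -> float:
    return float((weights * (means - mu_t) ** 2).sum())


def _exact_partition_score(counts: np.ndarray, combo: Sequence[int]) -> tuple[int, int]:
    """Exact rational sum_z S_z^2 / W_z for integer histogram counts.

    Returned as a (numerator, denominator) pair of Python ints; maximizing
    this quantity is equivalent to maximizing the between-region variance.
    """
    bounds = [-1, *combo, len(counts) - 1]
    num, den = 0, 1
    for a, b in zip(bounds[:-1], bounds[1:]):
        W = int(counts[a + 1 : b + 1].sum())
        if W == 0:
            continue
        S = int((counts[a + 1 : b + 1] * np.arange(a + 1, b + 1)).sum())
        num, den = num * W + S * S * den, den * W
    return num, den


def _exhaustive_argmax(
    hist: np.ndarray, p: np.ndarray, n_regions: int, mu_t: float
) -> tuple[int, ...]:
    """Vectorized scan of every strictly increasing threshold tuple.

    Tuples are enumerated in lexicographic order and the first maximizer
    kept.  Tuples whose float scores fall within rounding error of the
    maximum (e.g. thresholds lying in the same unoccupied gap, which induce
    the identical partition) are re-compared in exact rational arithmetic,
    so ties resolve to the lexicographically smallest tuple regardless of
    summation order.
    """
    L = p.size
    combos = np.array(
        list(itertools.combinations(range(L - 1), n_regions - 1)), dtype=int
    )
    cw = np.concatenate([[0.0], np.cumsum(p)])
    cs = np.concatenate([[0.0], np.cumsum(p * np.arange(L))])
    bounds = np.hstack(
        [np.full((combos.shape[0], 1), -1), combos, np.full((combos.shape[0], 1), L - 1)]
    )
    lo, hi = bounds[:, :-1] + 1, bounds[:, 1:] + 1
    w = cw[hi] - cw[lo]
    s = cs[hi] - cs[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(w > 0, s / np.maximum(w, 1e-300), 0.0)
    sigma_b2 = (w * (mu - mu_t) ** 2).sum(axis=1)
    best = float(sigma_b2.max())
    tol = 1e-9 * max(best, 1e-30)
    near = np.nonzero(sigma_b2 >= best - tol)[0]
    if near.size == 1 or not np.allclose(hist, np.rint(hist)):
        return tuple(int(t) for t in combos[near[0]])
    counts = np.rint(hist).astype(object)
    best_combo, best_num, best_den = None, None, None
    for idx in near:  # lexicographic order preserved by enumeration order
        combo = tuple(int(t) for t in combos[idx])
        num, den = _exact_partition_score(counts, combo)
        if best_combo is None or num * best_den > best_num * den:
            best_combo, best_num, best_den = combo, num, den
    return best_combo


def _dp_argmax(p: np.ndarray, n_regions: int, mu_t: float) -> tuple[int, ...]:
    """Contiguous-partition dynamic program on the occupied gray levels.

    Maximizes sum_z w_z (mu_z - mu_t)^2 over partitions of the occupied
    levels into ``n_regions`` runs; thresholds are reported as the last
    occupied level of each region (the lexicographically smallest gray
    levels realizing the partition).  Ties resolve toward earlier cuts.
    """
    occ = np.nonzero(p)[0]
    K = occ.size
    pv = p[occ]
    lv = occ.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(pv)])
    cs = np.concatenate([[0.0], np.cumsum(pv * lv)])
    # seg[i, j] = contribution of a region spanning occupied levels i..j
    i_idx = np.arange(K)[:, None]
    j_idx = np.arange(K)[None, :]
    w = cw[j_idx + 1] - cw[i_idx]
    s = cs[j_idx + 1] - cs[i_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(w > 0, s / np.maximum(w, 1e-300), 0.0)
    seg = np.where(j_idx >= i_idx, w * (mu - mu_t) ** 2, -np.inf)

    R = n_regions
    # f[j] = best value covering occ[0..j] with the current number of regions
    f = seg[0, :].copy()
    back: list[np.ndarray] = []
    for _ in range(1, R):
        # candidate: region starts at i (>=1), previous best ends at i-1
        cand = f[:-1, None] + seg[1:, :]  # cand[i-1, j] for i = 1..K-1
        # region start must be <= j: seg already -inf above the diagonal
        best_i = np.argmax(cand, axis=0)  # first max -> earliest cut
        newf = cand[best_i, np.arange(K)]
        newf[0] = -np.inf  # cannot split a single level further
        back.append(best_i + 1)
        f = newf
    # reconstruct boundaries (indices into occ of each region's last level)
    ends = []
    j = K - 1
    for z in range(R - 1, 0, -1):
        start = int(back[z - 1][j])
        ends.append(start - 1)
        j = start - 1
    ends.reverse()
    return tuple(int(occ[e]) for e in ends)


def multiregion_threshold(histogram: np.ndarray, n_regions: int) -> ThresholdSolution:
    """Optimal (R-1)-threshold partition maximizing between-region variance.

    ``histogram`` is a vector of gray-level counts over L levels.  Raises
    :class:`ZeroVarianceError` when a single level holds all mass and
    :class:`InfeasibleSplitError` when fewer than ``n_regions`` levels are
    occupied.  Ties resolve to the lexicographically smallest tuple.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be a 1-D vector with >= 2 levels")
    if not 2 <= n_regions <= 20:
        raise ValueError("n_regions must be in 2..20")
    if hist.sum() <= 0:
        raise ZeroVarianceError("empty histogram")
    occupied = np.nonzero(hist)[0]
    if occupied.size == 1:
        raise ZeroVarianceError("single occupied gray level: zero total variance")
    if occupied.size < n_regions:
        raise InfeasibleSplitError(
            f"{occupied.size} occupied levels cannot form {n_regions} regions"
        )
    p, mu_t, sigma_t2 = _histogram_moments(hist)
    if sigma_t2 == 0:
        raise ZeroVarianceError("zero total variance")

    L = hist.size
    n_tuples = math.comb(L - 1, n_regions - 1)
    if n_tuples <= _EXHAUSTIVE_CAP:
        thresholds = _exhaustive_argmax(hist, p, n_regions, mu_t)
    else:
        thresholds = _dp_argmax(p, n_regions, mu_t)

    weights, means = _region_stats(p, thresholds)
    # one occupied level per region: the partition explains all variance
    region_idx = np.searchsorted(np.asarray(thresholds), occupied, side="left")
    singletons = occupied.size == n_regions and len(set(region_idx)) == n_regions
    sigma_b2 = _between_variance(weights, means, mu_t)
    eta = 1.0 if singletons else min(sigma_b2 / sigma_t2, 1.0)
    if singletons:
        sigma_b2 = sigma_t2
    return ThresholdSolution(
        n_regions=n_regions,
        thresholds=tuple(int(t) for t in thresholds),
        tau_star=int(thresholds[0]),
        eta=float(eta),
        between_var=float(sigma_b2),
        total_var=float(sigma_t2),
        region_weights=tuple(float(w) for w in weights),
        region_means=tuple(float(m) for m in means),
        image_mean=float(mu_t),
        n_gray_levels=int(L),
    )


def adaptive_region_count(
    histogram: np.ndarray, eta_min: float = 0.8, r_max: int = 20
) -> ThresholdSolution:
    """Increase the region count R = 2, 3, ... until eta >= eta_min.

    Returns the first solution whose effectiveness reaches ``eta_min``, or
    the solution at ``r_max`` (or at the number of occupied levels, where
    eta is identically 1) when the target is never reached.  Simple
    few-mode histograms therefore stop at small R; near-uniform ones grow
    toward the cap.
    """
    sol: ThresholdSolution | None = None
    for r in range(2, r_max + 1):
        try:
            sol = multiregion_threshold(histogram, r)
        except InfeasibleSplitError:
            break  # fewer occupied levels than regions: keep last solution
        if sol.eta >= eta_min:
            break
    assert sol is not None  # R=2 either succeeded or raised ZeroVarianceError
    return sol


def _border_flags(binary: np.ndarray) -> tuple[bool, bool, bool, bool]:
    """Q = (left, top, right, bottom): does foreground touch each side?"""
    return (
        bool(binary[:, 0].any()),
        bool(binary[0, :].any()),
        bool(binary[:, -1].any()),
        bool(binary[-1, :].any()),
    )


def binarize_window(
    window: SegmentationWindow, solution: ThresholdSolution
) -> SegmentationWindow:
    """Keep the darkest stratum: foreground where W1 <= min(thresholds)."""
    window.binary = window.pixels <= solution.min_threshold
    window.border_flags = _border_flags(window.binary)
    return window


def select_candidate(window: SegmentationWindow) -> CandidateObject | None:
    """Keep the two largest components, return the one nearer the center.

    The center distance d_i is the minimum Euclidean distance from the
    window center to any pixel of object i (zero when the object covers the
    center).  Area ties keep the earlier label; distance ties keep the
    larger object.  Coordinates in the returned object are window-local.
    """
    if window.binary is None or not window.binary.any():
        return None
    lab = label(window.binary, connectivity=2)
    n = lab.max()
    areas = np.bincount(lab.ravel())[1:]  # per label 1..n
    order = sorted(range(1, n + 1), key=lambda l: (-areas[l - 1], l))
    keep = order[:2]
    cy, cx = window.center
    best: tuple[float, int, int] | None = None  # (distance, -area, label)
    for l in keep:
        coords = np.argwhere(lab == l)
        d = float(np.sqrt(((coords[:, 0] - cy) ** 2 + (coords[:, 1] - cx) ** 2)).min())
        key = (d, -int(areas[l - 1]), l)
        if best is None or key < best:
            best = key
    assert best is not None
    chosen = best[2]
    coords = np.argwhere(lab == chosen)
    return CandidateObject(
        pixel_coords=coords,
        area=int(areas[chosen - 1]),
        center_distance=best[0],
        source_seed=-1,
        final_bbox=window.bbox,
        mask=(lab == chosen),
    )


def grow_window(
    window: SegmentationWindow, search_space: np.ndarray
) -> tuple[BoundingBox, bool]:
    """Directional growth of the window vertices V under border flags Q.

    Sides whose flag is set move outward — left/top by 5 px, right/bottom
    by 10 px — provided every pixel of the moved edge lies inside the
    search space S (edges leaving the frame or S are frozen).  The
    continue-flag reports whether any side actually moved.
    """
    S = np.asarray(search_space, dtype=bool)
    h, w = S.shape
    b = window.bbox
    q1, q2, q3, q4 = window.border_flags
    v1, v2, v3, v4 = b.v1, b.v2, b.v3, b.v4
    moved = False

    if q1:
        nc = b.v1 - GROW_LEFT_TOP
        if nc >= 0 and S[b.v2 : b.v4 + 1, nc].all():
            v1, moved = nc, True
    if q2:
        nr = b.v2 - GROW_LEFT_TOP
        if nr >= 0 and S[nr, b.v1 : b.v3 + 1].all():
            v2, moved = nr, True
    if q3:
        nc = b.v3 + GROW_RIGHT_BOTTOM
        if nc <= w - 1 and S[b.v2 : b.v4 + 1, nc].all():
            v3, moved = nc, True
    if q4:
        nr = b.v4 + GROW_RIGHT_BOTTOM
        if nr <= h - 1 and S[nr, b.v1 : b.v3 + 1].all():
            v4, moved = nr, True

    return BoundingBox(v1, v2, v3, v4), moved


def _to_image_frame(
    obj: CandidateObject, bbox: BoundingBox, shape: tuple[int, int],
    seed_id: int, converged: bool
) -> CandidateObject:
    coords = obj.pixel_coords + np.array([bbox.v2, bbox.v1])
    mask = np.zeros(shape, dtype=bool)
    mask[coords[:, 0], coords[:, 1]] = True
    return CandidateObject(
        pixel_coords=coords,
        area=obj.area,
        center_distance=obj.center_distance,
        source_seed=seed_id,
        final_bbox=bbox,
        mask=mask,
        converged=converged,
    )


def segment_from_seed(
    calibrated: np.ndarray,
    seed: SeedPoint,
    search_space: np.ndarray,
    max_iters: int = 50,
    seed_id: int = -1,
    eta_min: float = 0.8,
    r_max: int = 20,
    seed_pad: int = 0,
) -> CandidateObject | None:
    """Run the SWAT loop from one seed's bounding box.

    ``seed_pad`` expands the initial window on every side so that a seed
    core lying fully inside a large lesion still sees some of the bright
    surround (a window with no surround degenerates to thresholding noise).

    Crop -> adaptive multi-region threshold -> darkest-stratum binarization
    -> keep-two / nearest-center selection -> recompute border flags from
    the selected object -> directional growth, until the flags clear or
    ``max_iters`` is hit (the object is then flagged non-converged).
    Returns ``None`` for windows with no intensity structure or no dark
    foreground.
    """
    img = as_gray_u8(calibrated)
    b = seed.bbox
    bbox = BoundingBox(b.v1 - seed_pad, b.v2 - seed_pad,
                       b.v3 + seed_pad, b.v4 + seed_pad).clipped(img.shape)
    obj: CandidateObject | None = None
    converged = False
    for _ in range(max_iters):
        window = SegmentationWindow(bbox=bbox, pixels=bbox.crop(img))
        hist = np.bincount(window.pixels.ravel(), minlength=256)
        try:
            sol = adaptive_region_count(hist, eta_min=eta_min, r_max=r_max)
        except ZeroVarianceError:
            return None
        binarize_window(window, sol)
        obj = select_candidate(window)
        if obj is None:
            return None
        window.border_flags = _border_flags(obj.mask)
        if not any(window.border_flags):
            converged = True
            break
        new_bbox, moved = grow_window(window, search_space)
        if not moved:
            break  # all touched sides blocked by S or the frame
        bbox = new_bbox
    if obj is None:
        return None
    return _to_image_frame(obj, bbox, img.shape, seed_id, converged)


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    union = np.logical_or(a, b).sum()
    return float(inter) / float(union)


def segment_all(
    calibrated: np.ndarray,
    seeds: Sequence[SeedPoint],
    search_space: np.ndarray,
    max_iters: int = 50,
    dedup_iou: float = 0.8,
    seed_pad: int = 0,
) -> list[CandidateObject]:
    """Segment every seed, drop failures, deduplicate overlapping objects.

    Objects whose masks overlap with IoU above ``dedup_iou`` are collapsed
    to the larger one (ties keep the earlier seed).
    """
    objects: list[CandidateObject] = []
    for i, seed in enumerate(seeds):
        obj = segment_from_seed(
            calibrated, seed, search_space, max_iters=max_iters, seed_id=i,
            seed_pad=seed_pad,
        )
        if obj is not None:
            objects.append(obj)
    order = sorted(range(len(objects)), key=lambda i: (-objects[i].area, i))
    kept: list[CandidateObject] = []
    for i in order:
        if all(_mask_iou(objects[i].mask, k.mask) <= dedup_iou for k in kept):
            kept.append(objects[i])
    kept.sort(key=lambda o: o.source_seed)
    return kept
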