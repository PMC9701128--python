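"""Smart-window adaptive thresholding: oracles, contracts, geometry."""

import itertools

import numpy as np
import pytest

from hemseg.swat import (
    GROW_LEFT_TOP,
    GROW_RIGHT_BOTTOM,
    adaptive_region_count,
    binarize_window,
    grow_window,
    multiregion_threshold,
    segment_all,
    segment_from_seed,
    select_candidate,
)
from hemseg.types import (
    BoundingBox,
    InfeasibleSplitError,
    SeedPoint,
    SegmentationWindow,
    ZeroVarianceError,
)
from tests.conftest import make_disc


def brute_force_best_tuple(hist, n_regions):
    """Independent exhaustive maximization of the between-region variance.

    Evaluates every strictly increasing threshold tuple in lexicographic
    order with strict improvement, so ties keep the lexicographically
    smallest tuple.  Maximizing sum_z w_z (mu_z - mu_T)^2 is equivalent to
    maximizing sum_z S_z^2 / W_z over integer count sums S (count*level)
    and W (count), which is compared here in exact rational arithmetic so
    equal-partition gap ties are genuinely equal.  Returns the best tuple
    and its between-region variance as a float.
    """
    counts = [int(round(c)) for c in np.asarray(hist, dtype=float)]
    L = len(counts)
    best_num, best_den, best_tuple = None, None, None
    for combo in itertools.combinations(range(L - 1), n_regions - 1):
        bounds = [-1, *combo, L - 1]
        num, den = 0, 1  # running exact sum of S_z^2 / W_z
        for a, b in zip(bounds[:-1], bounds[1:]):
            W = sum(counts[a + 1 : b + 1])
            if W == 0:
                continue
            S = sum(l * counts[l] for l in range(a + 1, b + 1))
            num, den = num * W + S * S * den, den * W
        if best_num is None or num * best_den > best_num * den:
            best_num, best_den, best_tuple = num, den, combo
    n_total = sum(counts)
    s_total = sum(l * c for l, c in enumerate(counts))
    mu_t = s_total / n_total
    best_val = best_num / best_den / n_total - mu_t**2
    return best_tuple, best_val


def random_histogram(rng, max_levels=32):
    L = int(rng.integers(8, max_levels + 1))
    hist = rng.integers(0, 60, size=L)
    if np.count_nonzero(hist) < 5:
        hist[rng.integers(0, L, size=5)] += 1
    return hist


class TestMultiregionThreshold:
    def test_two_valued_histogram_full_effectiveness(self):
        hist = np.zeros(256)
        hist[50], hist[200] = 500, 500
        sol = multiregion_threshold(hist, 2)
        assert 50 <= sol.thresholds[0] < 200
        assert sol.eta == pytest.approx(1.0)
        assert sol.tau_star == sol.thresholds[0]

    def test_three_region_toy_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        hist = np.zeros(16)
        hist[[2, 3, 8, 9, 13, 14]] = [40, 30, 55, 45, 35, 25]
        sol = multiregion_threshold(hist, 3)
        oracle, _ = brute_force_best_tuple(hist, 3)
        assert sol.thresholds == oracle

    def test_constant_histogram_rejected(self):
        hist = np.zeros(32)
        hist[7] = 100
        with pytest.raises(ZeroVarianceError):
            multiregion_threshold(hist, 2)

    def test_too_few_occupied_levels_rejected(self):
        hist = np.zeros(32)
        hist[[3, 20]] = 10
        with pytest.raises(InfeasibleSplitError):
            multiregion_threshold(hist, 3)

    def test_invalid_region_counts_rejected(self):
        hist = np.ones(32)
        for r in (1, 21):
            with pytest.raises(ValueError):
                multiregion_threshold(hist, r)

    def test_solution_invariants_on_random_histograms(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            hist = random_histogram(rng)
            r = int(rng.integers(2, 5))
            if np.count_nonzero(hist) < r:
                continue
            sol = multiregion_threshold(hist, r)
            assert all(a < b for a, b in zip(sol.thresholds, sol.thresholds[1:]))
            assert sol.region_weights == pytest.approx(
                tuple(np.array(sol.region_weights)), abs=0
            )
            assert sum(sol.region_weights) == pytest.approx(1.0)
            assert 0.0 <= sol.eta <= 1.0
            # weighted region means recompose the global mean
            recomposed = sum(w * m for w, m in zip(sol.region_weights, sol.region_means))
            assert recomposed == pytest.approx(sol.image_mean, abs=1e-9)

    def test_dp_path_agrees_with_exhaustive_on_moderate_instance(self):
        """Force the dynamic program and compare against brute force."""
        import hemseg.swat as sw

        rng = np.random.default_rng(2)
        hist = np.zeros(24)
        occ = rng.choice(24, size=12, replace=False)
        hist[occ] = rng.integers(1, 50, size=12)
        sol_exh = multiregion_threshold(hist, 4)
        old_cap = sw._EXHAUSTIVE_CAP
        try:
            sw._EXHAUSTIVE_CAP = 0  # force DP
            sol_dp = multiregion_threshold(hist, 4)
        finally:
            sw._EXHAUSTIVE_CAP = old_cap
        assert sol_dp.between_var == pytest.approx(sol_exh.between_var, rel=1e-12)


class TestAdaptiveRegionCount:
    def test_two_valued_stops_immediately(self):
        hist = np.zeros(256)
        hist[30], hist[220] = 100, 300
        sol = adaptive_region_count(hist)
        assert sol.n_regions == 2
        assert sol.eta == pytest.approx(1.0)

    def test_three_separated_modes_need_three_regions(self):
        rng = np.random.default_rng(3)
        hist = np.zeros(64)
        for center in (8, 30, 55):
            for off in (-1, 0, 1):
                hist[center + off] = 100
        sol = adaptive_region_count(hist)
        # oracle: first R whose optimal eta crosses 0.8
        first = None
        for r in range(2, 21):
            s = multiregion_threshold(hist, r)
            if s.eta >= 0.8:
                first = r
                break
        assert sol.n_regions == first == 3

    def test_returns_first_crossing_on_random_histograms(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            hist = random_histogram(rng)
            sol = adaptive_region_count(hist)
            first = None
            for r in range(2, 21):
                try:
                    s = multiregion_threshold(hist, r)
                except InfeasibleSplitError:
                    break
                if s.eta >= 0.8:
                    first = r
                    break
            assert first == sol.n_regions
            assert sol.eta >= 0.8

    def test_eta_monotone_in_region_count(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            hist = random_histogram(rng)
            K = np.count_nonzero(hist)
            etas = [
                multiregion_threshold(hist, r).eta for r in range(2, min(6, K + 1))
            ]
            assert all(b >= a - 1e-9 for a, b in zip(etas, etas[1:]))


class TestBinarizeWindow:
    def _window(self, pixels):
        return SegmentationWindow(
            bbox=BoundingBox(0, 0, pixels.shape[1] - 1, pixels.shape[0] - 1),
            pixels=pixels,
        )

    def test_darkest_stratum_is_foreground_inclusive(self):
        px = np.array([[10, 50], [120, 200]], dtype=np.uint8)
        hist = np.bincount(px.ravel(), minlength=256)
        sol = multiregion_threshold(hist, 2)
        win = binarize_window(self._window(px), sol)
        # pixels at exactly min(thresholds) stay foreground (rule is > for bg)
        assert win.binary[px <= sol.min_threshold].all()
        assert not win.binary[px > sol.min_threshold].any()

    def test_all_above_threshold_gives_empty_foreground(self):
        px = np.full((6, 6), 150, dtype=np.uint8)
        px[0, 0] = 10  # one dark pixel defines the stratum
        hist = np.bincount(px.ravel(), minlength=256)
        sol = multiregion_threshold(hist, 2)
        win = self._window(np.full((6, 6), 200, dtype=np.uint8))
        win = binarize_window(win, sol)
        assert not win.binary.any()
        assert win.border_flags == (False, False, False, False)

    def test_dark_disc_recovered(self):
        px = np.full((41, 41), 200, dtype=np.uint8)
        disc = make_disc((41, 41), (20, 20), 12)
        px[disc] = 30
        hist = np.bincount(px.ravel(), minlength=256)
        sol = adaptive_region_count(hist)
        win = binarize_window(self._window(px), sol)
        assert np.array_equal(win.binary, disc)


class TestSelectCandidate:
    def _window_from_mask(self, mask):
        win = SegmentationWindow(
            bbox=BoundingBox(0, 0, mask.shape[1] - 1, mask.shape[0] - 1),
            pixels=np.zeros(mask.shape, dtype=np.uint8),
        )
        win.binary = mask
        return win

    def test_empty_binary_returns_none(self):
        assert select_candidate(self._window_from_mask(np.zeros((9, 9), bool))) is None

    def test_centered_object_has_zero_distance(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[8:13, 8:13] = True
        obj = select_candidate(self._window_from_mask(mask))
        assert obj.center_distance == 0.0
        assert obj.area == 25

    def test_central_small_beats_peripheral_large(self):
        mask = np.zeros((41, 61), dtype=bool)
        mask[18:23, 25:36] = True  # 55 px blob over the center
        mask[0:30, 0:20] = True  # 600 px blob in the corner
        obj = select_candidate(self._window_from_mask(mask))
        # brute-force min distance over the central blob's pixels
        cy, cx = (41 - 1) / 2, (61 - 1) / 2
        small = np.zeros_like(mask)
        small[18:23, 25:36] = True
        d_small = min(np.hypot(r - cy, c - cx) for r, c in np.argwhere(small))
        assert obj.center_distance == pytest.approx(d_small)
        assert obj.area == 55

    def test_keep_two_stage_discards_central_speck(self):
        mask = np.zeros((31, 31), dtype=bool)
        mask[15, 15] = True  # central single-pixel speck
        mask[0:10, 0:12] = True  # 120 px
        mask[21:31, 19:31] = True  # 120 px
        obj = select_candidate(self._window_from_mask(mask))
        # the two largest blobs exclude the nearest (speck) object
        assert obj.area == 120

    def test_matches_bruteforce_on_random_layouts(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            mask = np.zeros((25, 25), dtype=bool)
            # two random rectangles
            rects = []
            for _ in range(2):
                r0, c0 = rng.integers(0, 18, size=2)
                h, w = rng.integers(2, 7, size=2)
                mask[r0 : r0 + h, c0 : c0 + w] = True
            obj = select_candidate(self._window_from_mask(mask))
            from skimage.measure import label as sklabel

            lab = sklabel(mask, connectivity=2)
            areas = np.bincount(lab.ravel())[1:]
            order = sorted(range(1, lab.max() + 1), key=lambda l: (-areas[l - 1], l))
            keep = order[:2]
            cy = cx = 12.0
            best = None
            for l in keep:
                coords = np.argwhere(lab == l)
                d = min(np.hypot(r - cy, c - cx) for r, c in coords)
                key = (d, -areas[l - 1], l)
                if best is None or key < best:
                    best = key
            assert obj.center_distance == pytest.approx(best[0])
            assert obj.area == areas[best[2] - 1]


class TestGrowWindow:
    def _win(self, bbox, flags):
        win = SegmentationWindow(
            bbox=bbox, pixels=np.zeros((bbox.height, bbox.width), dtype=np.uint8)
        )
        win.border_flags = flags
        return win

    def test_no_flags_no_growth(self):
        S = np.ones((100, 100), dtype=bool)
        bbox = BoundingBox(40, 40, 60, 60)
        new, moved = grow_window(self._win(bbox, (False,) * 4), S)
        assert new == bbox and not moved

    def test_left_flag_moves_left_edge_only(self):
        S = np.ones((100, 100), dtype=bool)
        bbox = BoundingBox(40, 40, 60, 60)
        new, moved = grow_window(self._win(bbox, (True, False, False, False)), S)
        assert moved
        assert (new.v1, new.v2, new.v3, new.v4) == (40 - GROW_LEFT_TOP, 40, 60, 60)

    def test_all_flags_apply_asymmetric_amounts(self):
        S = np.ones((200, 200), dtype=bool)
        bbox = BoundingBox(50, 60, 90, 100)
        new, moved = grow_window(self._win(bbox, (True,) * 4), S)
        assert moved
        assert new == BoundingBox(
            50 - GROW_LEFT_TOP, 60 - GROW_LEFT_TOP,
            90 + GROW_RIGHT_BOTTOM, 100 + GROW_RIGHT_BOTTOM,
        )

    def test_search_space_blocks_one_side(self):
        S = np.ones((200, 200), dtype=bool)
        S[:, 95:] = False  # right expansion (to col 100) leaves S
        bbox = BoundingBox(50, 60, 90, 100)
        new, moved = grow_window(self._win(bbox, (False, False, True, True)), S)
        assert moved
        assert new == BoundingBox(50, 60, 90, 100 + GROW_RIGHT_BOTTOM)

    def test_blocked_on_all_sides_halts(self):
        S = np.zeros((200, 200), dtype=bool)
        bbox = BoundingBox(50, 60, 90, 100)
        S[60:101, 50:91] = True  # S exactly the window
        new, moved = grow_window(self._win(bbox, (True,) * 4), S)
        assert new == bbox and not moved

    def test_frame_edge_freezes_side(self):
        S = np.ones((120, 120), dtype=bool)
        bbox = BoundingBox(2, 2, 110, 110)
        new, moved = grow_window(self._win(bbox, (True, True, True, True)), S)
        # left/top would go negative: frozen; right/bottom hit frame: frozen
        assert (new.v1, new.v2) == (2, 2)
        assert (new.v3, new.v4) == (110, 110)
        assert not moved


class TestSegmentFromSeed:
    def test_isolated_dark_disc_converges_first_iteration(self):
        img = np.full((120, 120), 190, dtype=np.uint8)
        disc = make_disc((120, 120), (60, 60), 14)
        img[disc] = 40
        seed = SeedPoint(bbox=BoundingBox(38, 38, 82, 82), centroid=(60.0, 60.0), area=100)
        S = np.ones((120, 120), dtype=bool)
        obj = segment_from_seed(img, seed, S)
        assert obj is not None and obj.converged
        iou = (obj.mask & disc).sum() / (obj.mask | disc).sum()
        assert iou >= 0.9
        assert obj.final_bbox == seed.bbox  # no growth needed

    def test_object_larger_than_seed_bbox_grows(self):
        img = np.full((160, 160), 190, dtype=np.uint8)
        disc = make_disc((160, 160), (80, 80), 30)
        img[disc] = 40
        seed = SeedPoint(bbox=BoundingBox(70, 70, 90, 90), centroid=(80.0, 80.0), area=50)
        S = np.ones((160, 160), dtype=bool)
        # seed_pad gives the interior window a view of the bright surround,
        # as in the pipeline configuration (a constant crop has no threshold)
        obj = segment_from_seed(img, seed, S, seed_pad=12)
        assert obj is not None
        b, s0 = obj.final_bbox, seed.bbox
        assert b.v1 <= s0.v1 and b.v2 <= s0.v2 and b.v3 >= s0.v3 and b.v4 >= s0.v4
        assert (b.v1, b.v2, b.v3, b.v4) != (s0.v1, s0.v2, s0.v3, s0.v4)
        iou = (obj.mask & disc).sum() / (obj.mask | disc).sum()
        assert iou >= 0.8

    def test_constant_window_returns_none(self):
        img = np.full((60, 60), 120, dtype=np.uint8)
        seed = SeedPoint(bbox=BoundingBox(20, 20, 40, 40), centroid=(30.0, 30.0), area=10)
        assert segment_from_seed(img, seed, np.ones((60, 60), bool)) is None

    def test_long_dark_stripe_is_bounded_by_search_space_or_iters(self):
        img = np.full((120, 400), 190, dtype=np.uint8)
        img[55:65, :] = 40  # vessel-like stripe across the image
        seed = SeedPoint(bbox=BoundingBox(190, 50, 215, 70), centroid=(60.0, 200.0), area=50)
        S = np.zeros((120, 400), dtype=bool)
        S[:, 100:300] = True  # admissible region ends at columns 100/300
        obj = segment_from_seed(img, seed, S, max_iters=50)
        # growth marches along the stripe until S freezes both ends
        assert obj is not None
        assert obj.final_bbox.v1 >= 95 and obj.final_bbox.v3 <= 305
        assert not obj.converged  # stripe still touches the window sides

    def test_iteration_cap_flags_nonconvergence(self):
        img = np.full((120, 400), 190, dtype=np.uint8)
        img[55:65, :] = 40
        seed = SeedPoint(bbox=BoundingBox(190, 50, 215, 70), centroid=(60.0, 200.0), area=50)
        S = np.ones((120, 400), dtype=bool)
        obj = segment_from_seed(img, seed, S, max_iters=3)
        assert obj is not None and not obj.converged

    def test_bbox_always_inside_frame(self, products, seeds, candidates):
        h, w = products.calibrated_image.shape
        for obj in candidates:
            b = obj.final_bbox
            assert 0 <= b.v1 <= b.v3 <= w - 1
            assert 0 <= b.v2 <= b.v4 <= h - 1

    def test_dark_object_contract(self, products, candidates):
        cal = products.calibrated_image.astype(float)
        for obj in candidates:
            b = obj.final_bbox
            window = cal[b.v2 : b.v4 + 1, b.v1 : b.v3 + 1]
            assert cal[obj.mask].mean() < window.mean()


class TestSegmentAll:
    def test_empty_seed_list(self, products):
        assert segment_all(products.calibrated_image, [], products.search_space) == []

    def test_two_seeds_on_same_lesion_deduplicate(self):
        img = np.full((120, 120), 190, dtype=np.uint8)
        disc = make_disc((120, 120), (60, 60), 14)
        img[disc] = 40
        s1 = SeedPoint(bbox=BoundingBox(40, 40, 80, 80), centroid=(60.0, 60.0), area=80)
        s2 = SeedPoint(bbox=BoundingBox(42, 42, 82, 82), centroid=(61.0, 61.0), area=70)
        objs = segment_all(img, [s1, s2], np.ones((120, 120), bool))
        assert len(objs) == 1

    def test_separate_lesions_all_reported(self):
        img = np.full((120, 240), 190, dtype=np.uint8)
        discs = [make_disc((120, 240), c, 12) for c in [(40, 50), (80, 120), (40, 190)]]
        for d in discs:
            img[d] = 40
        seeds_list = [
            SeedPoint(bbox=BoundingBox(c[1] - 16, c[0] - 16, c[1] + 16, c[0] + 16),
                      centroid=(float(c[0]), float(c[1])), area=60)
            for c in [(40, 50), (80, 120), (40, 190)]
        ]
        objs = segment_all(img, seeds_list, np.ones((120, 240), bool))
        assert len(objs) == 3
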