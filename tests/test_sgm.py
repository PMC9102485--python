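"""Semi-global matcher: census cost, path aggregation vs brute force, winner
selection, consistency checking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stereovol import (
    SGMParams,
    aggregate_paths,
    census_transform,
    compute_disparity,
    cross_check,
    matching_cost,
    render_stereo_pair,
    select_disparity,
)
from stereovol.sgm import CostVolume, DisparityMap, aggregate_single_path


def enumerate_path_costs(C_row: np.ndarray, P1: int, P2: int) -> np.ndarray:
    """Brute force: min total cost over ALL disparity sequences of one row.

    Returns DP[c, d] = min over sequences (d_0..d_c) ending at d of
    sum_i C(i, d_i) + sum transitions, with transition cost 0 / P1 / P2 for
    disparity changes of 0 / 1 / >1 levels.  Pure enumeration, O(D^W).
    """
    W, D = C_row.shape
    best = np.full((W, D), np.inf)
    for seq in itertools.product(range(D), repeat=W):
        cost = 0.0
        for i, d in enumerate(seq):
            cost += C_row[i, d]
            if i > 0:
                jump = abs(d - seq[i - 1])
                cost += 0 if jump == 0 else (P1 if jump == 1 else P2)
            if cost < best[i, d]:
                # a full sequence's prefix is itself a valid sequence
                best[i, d] = min(best[i, d], cost)
        best[W - 1, seq[-1]] = min(best[W - 1, seq[-1]], cost)
    return best


def dp_oracle(C_row: np.ndarray, P1: int, P2: int) -> np.ndarray:
    """Textbook forward dynamic program over one row (independent recursion)."""
    W, D = C_row.shape
    DP = np.zeros((W, D))
    DP[0] = C_row[0]
    for c in range(1, W):
        for d in range(D):
            trans = [
                DP[c - 1, k] + (0 if k == d else (P1 if abs(k - d) == 1 else P2))
                for k in range(D)
            ]
            DP[c, d] = C_row[c, d] + min(trans)
    return DP


class TestCensus:
    def test_constant_image_all_zero(self):
        assert (census_transform(np.full((6, 6), 9.0), 3) == 0).all()

    def test_hand_evaluated_3x3_patch(self):
        """Center 5: the four smaller neighbors set the leading bits."""
        img = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
        code = census_transform(img, 3)[1, 1]
        # neighbor order row-major skipping center: 1,2,3,4,6,7,8,9
        bits = [(int(code) >> i) & 1 for i in range(8)]
        assert bits == [1, 1, 1, 1, 0, 0, 0, 0]

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 200, (10, 12))
        np.testing.assert_array_equal(
            census_transform(img, 5), census_transform(img + 37.5, 5)
        )

    def test_window_validation(self):
        with pytest.raises(ValueError):
            census_transform(np.zeros((10, 10)), 4)
        with pytest.raises(ValueError):
            census_transform(np.zeros((4, 4)), 7)


class TestMatchingCost:
    def _params(self, **kw):
        kw.setdefault("d_min", 0)
        kw.setdefault("d_max", 4)
        return SGMParams(**kw)

    def test_identical_images_zero_cost_at_d0(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (12, 20))
        c = census_transform(img, 5)
        C = matching_cost(c, c, self._params()).C
        assert (C[:, :, 0] == 0).all()

    def test_pure_shift_recovered(self):
        """Right = left shifted 3 px -> cost argmin is 3 at interior pixels."""
        rng = np.random.default_rng(2)
        left = rng.uniform(0, 255, (15, 30))
        right = np.empty_like(left)
        right[:, :-3] = left[:, 3:]
        right[:, -3:] = left[:, :3]
        cl = census_transform(left, 5)
        cr = census_transform(right, 5)
        C = matching_cost(cl, cr, self._params()).C
        winners = C[4:-4, 8:-8].argmin(axis=-1)
        assert (winners == 3).mean() > 0.95

    def test_cost_bounded_by_window(self):
        rng = np.random.default_rng(3)
        a = census_transform(rng.uniform(0, 255, (10, 15)), 5)
        b = census_transform(rng.uniform(0, 255, (10, 15)), 5)
        C = matching_cost(a, b, self._params()).C
        assert C.max() <= 24 and C.min() >= 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            matching_cost(np.zeros((5, 5), np.uint64), np.zeros((6, 5), np.uint64),
                          self._params())


class TestAggregation:
    def test_zero_penalties_degenerate_to_scaled_cost(self):
        rng = np.random.default_rng(4)
        C = rng.integers(0, 24, (6, 7, 5)).astype(np.int32)
        params = SGMParams(d_min=0, d_max=4, P1=0, P2=0, n_paths=8)
        S = aggregate_paths(CostVolume(C=C), params).S
        np.testing.assert_array_equal(S, 8 * C)

    def test_uniform_cost_stays_uniform(self):
        C = np.full((5, 6, 4), 7, dtype=np.int32)
        params = SGMParams(d_min=0, d_max=3, P1=2, P2=9, n_paths=4)
        S = aggregate_paths(CostVolume(C=C), params).S
        np.testing.assert_array_equal(S, 4 * C)

    def test_single_path_equals_exhaustive_enumeration(self):
        """Raw single-path aggregation == enumeration over all sequences."""
        rng = np.random.default_rng(5)
        C = rng.integers(0, 20, (1, 6, 4)).astype(np.int32)
        params = SGMParams(d_min=0, d_max=3, P1=1, P2=2)
        L = aggregate_single_path(CostVolume(C=C), params, (0, 1), normalize=False)
        expected = enumerate_path_costs(C[0], 1, 2)
        np.testing.assert_allclose(L[0], expected)

    @pytest.mark.parametrize("shape,p1,p2,seed", [
        ((1, 5, 3), 1, 2, 0),
        ((8, 8, 5), 3, 11, 1),
        ((4, 8, 5), 0, 0, 2),
        ((8, 6, 4), 5, 5, 3),
    ])
    def test_single_path_equals_dp_oracle(self, shape, p1, p2, seed):
        """Each image row independently matches the textbook DP, exactly."""
        rng = np.random.default_rng(seed)
        C = rng.integers(0, 24, shape).astype(np.int32)
        params = SGMParams(d_min=0, d_max=shape[2] - 1, P1=p1, P2=p2)
        L = aggregate_single_path(CostVolume(C=C), params, (0, 1), normalize=False)
        for r in range(shape[0]):
            np.testing.assert_allclose(L[r], dp_oracle(C[r], p1, p2))

    def test_normalization_shifts_by_previous_pixel_minimum(self):
        """Normalized L(p,d) = raw DP(p,d) - min_k DP(p-1,k): a per-pixel
        constant that never changes the winner."""
        rng = np.random.default_rng(6)
        C = rng.integers(0, 24, (2, 7, 5)).astype(np.int32)
        params = SGMParams(d_min=0, d_max=4, P1=2, P2=8)
        Ln = aggregate_single_path(CostVolume(C=C), params, (0, 1), normalize=True)
        for r in range(2):
            DP = dp_oracle(C[r], 2, 8)
            expected = DP.copy()
            expected[1:] -= DP[:-1].min(axis=1, keepdims=True)
            np.testing.assert_allclose(Ln[r], expected)
            assert (Ln[r].argmin(axis=1) == DP.argmin(axis=1)).all()

    def test_reverse_direction_matches_mirrored_dp(self):
        rng = np.random.default_rng(7)
        C = rng.integers(0, 24, (3, 6, 4)).astype(np.int32)
        params = SGMParams(d_min=0, d_max=3, P1=1, P2=4)
        L = aggregate_single_path(CostVolume(C=C), params, (0, -1), normalize=False)
        for r in range(3):
            np.testing.assert_allclose(L[r], dp_oracle(C[r, ::-1], 1, 4)[::-1])

    def test_s_dominates_c_and_stays_finite(self):
        rng = np.random.default_rng(8)
        C = rng.integers(0, 24, (10, 12, 6)).astype(np.int32)
        params = SGMParams(d_min=0, d_max=5, P1=4, P2=30, n_paths=8)
        S = aggregate_paths(CostVolume(C=C), params).S
        assert (S >= C).all()
        assert np.isfinite(S).all()

    def test_p1_greater_than_p2_rejected(self):
        with pytest.raises(ValueError):
            SGMParams(d_min=0, d_max=3, P1=10, P2=5)


class TestSelectDisparity:
    def _cost(self, S, d_min=0):
        S = np.asarray(S, dtype=np.int32)[None, None, :]
        return CostVolume(C=S, S=S, d_min=d_min)

    def test_symmetric_neighbors_keep_integer_winner(self):
        disp = select_disparity(self._cost([9, 2, 9]), SGMParams(d_min=0, d_max=2))
        assert disp.disparity[0, 0] == pytest.approx(1.0)

    def test_parabola_vertex_hand_value(self):
        """S = (10, 2, 6) around the winner -> offset (10-6)/(2*(10-4+6)) = 1/6."""
        disp = select_disparity(self._cost([10, 2, 6]), SGMParams(d_min=0, d_max=2))
        assert disp.disparity[0, 0] == pytest.approx(1 + 4 / 24)

    def test_all_equal_ties_break_to_d_min(self):
        disp = select_disparity(self._cost([5, 5, 5, 5], d_min=2),
                                SGMParams(d_min=2, d_max=5))
        assert disp.disparity[0, 0] == 2.0

    def test_range_end_winner_stays_integer(self):
        disp = select_disparity(self._cost([1, 5, 9]), SGMParams(d_min=0, d_max=2))
        assert disp.disparity[0, 0] == 0.0

    def test_output_within_search_range(self):
        rng = np.random.default_rng(9)
        S = rng.integers(0, 100, (20, 20, 7)).astype(np.int32)
        params = SGMParams(d_min=3, d_max=9)
        disp = select_disparity(CostVolume(C=S, S=S, d_min=3), params)
        assert disp.disparity.min() >= 3 - 0.5 and disp.disparity.max() <= 9 + 0.5


class TestCrossCheck:
    def test_identical_constant_maps_all_valid(self):
        d = np.full((10, 30), 5.0)
        m = DisparityMap(disparity=d, valid=np.ones_like(d, bool))
        ok = cross_check(m, m, tol=0.5)
        assert ok[:, 5:].all()

    def test_infinite_tolerance_keeps_all_in_bounds(self):
        rng = np.random.default_rng(10)
        dl = rng.uniform(2, 6, (8, 20))
        dr = rng.uniform(2, 6, (8, 20))
        ml = DisparityMap(disparity=dl, valid=np.ones_like(dl, bool))
        mr = DisparityMap(disparity=dr, valid=np.ones_like(dr, bool))
        ok = cross_check(ml, mr, tol=np.inf)
        cols = np.arange(20)[None, :]
        inb = np.rint(cols - dl) >= 0
        np.testing.assert_array_equal(ok, inb)

    def test_occluded_band_invalidated_on_simulator_scene(self, small_rig):
        """Pixels the right camera cannot see fail the left-right check.

        A tall slab is used so the occlusion band spans whole pixels (an
        80 mm step at this rig's geometry is a ~2.4 px disparity jump)."""
        from stereovol import SceneSpec, ShapePrimitive
        from stereovol.pipeline import default_sgm_params

        tall = ShapePrimitive("slab", dict(size_x=100, size_y=100, height=300),
                              position=(76, 0))
        left, right, gt = render_stereo_pair(
            SceneSpec(primitives=(tall,), seed=3), small_rig
        )
        disp = compute_disparity(left, right, default_sgm_params(small_rig))
        overlap = np.zeros_like(gt.occlusion_mask)
        overlap[:, 55:] = True  # ignore the no-overlap margin
        occluded = gt.occlusion_mask & overlap
        visible = ~gt.occlusion_mask & overlap
        assert occluded.sum() > 50
        # occlusions are invalidated; the matcher's window blur fattens the
        # foreground over part of the band, so the contrast with visible
        # pixels is the meaningful check
        assert disp.valid[occluded].mean() < 0.6
        assert disp.valid[visible].mean() > 0.9
        assert disp.valid[occluded].mean() < 0.5 * disp.valid[visible].mean()


class TestEndToEndMatching:
    def test_textured_scene_disparity_accuracy(self, small_rig, small_slab_scene):
        """>= 90% of valid non-occluded ROI pixels within 1 px of ground truth."""
        left, right, gt = render_stereo_pair(small_slab_scene, small_rig)
        from stereovol.pipeline import default_sgm_params

        disp = compute_disparity(left, right, default_sgm_params(small_rig))
        m = gt.roi_mask & ~gt.occlusion_mask & disp.valid
        err = np.abs(disp.disparity[m] - gt.disparity_map[m])
        assert (err <= 1.0).mean() >= 0.90

    def test_textureless_scene_degrades(self, small_rig, small_slab_scene):
        left, right, gt = render_stereo_pair(small_slab_scene, small_rig,
                                             pattern_on=False)
        from stereovol.pipeline import default_sgm_params

        disp = compute_disparity(left, right, default_sgm_params(small_rig))
        m = gt.roi_mask & ~gt.occlusion_mask
        d = disp.disparity
        good = np.isfinite(d[m]) & (np.abs(d[m] - gt.disparity_map[m]) <= 1.0)
        assert good.mean() < 0.5
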