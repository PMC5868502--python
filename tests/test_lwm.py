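"""Locally weighted mean transform: fitting, evaluation, warping."""

import numpy as np
import pytest

from irtbat.errors import TransformError
from irtbat.lwm import (
    ControlPointPairs,
    LwmTransform,
    apply_lwm,
    fit_lwm,
    lwm_weight,
    warp_image,
    warp_polygon,
)
from irtbat.synthetic import poly2_eval


def grid_points(n_side=6, lo=0.0, hi=100.0, jitter_seed=None):
    g = np.linspace(lo, hi, n_side)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    if jitter_seed is not None:
        pts = pts + np.random.default_rng(jitter_seed).uniform(-2, 2, pts.shape)
    return pts


def random_quadratic(seed):
    """Random gentle global degree-2 warp (2×6 coeffs, near-affine)."""
    rng = np.random.default_rng(seed)
    affine = np.array([
        [rng.uniform(-5, 5), rng.uniform(0.8, 1.2), rng.uniform(-0.2, 0.2)],
        [rng.uniform(-5, 5), rng.uniform(-0.2, 0.2), rng.uniform(0.8, 1.2)],
    ])
    quad = rng.uniform(-5e-4, 5e-4, size=(2, 3))
    return np.hstack([affine, quad])


class TestWeightFunction:
    def test_endpoint_values(self):
        assert lwm_weight(0.0) == 1.0
        assert lwm_weight(1.0) == 0.0
        assert lwm_weight(1.5) == 0.0

    def test_monotone_decreasing_and_c1(self):
        t = np.linspace(0, 1, 1001)
        w = lwm_weight(t)
        assert np.all(np.diff(w) <= 0)
        # derivative → 0 at both ends (smooth taper)
        assert abs((w[1] - w[0]) / (t[1] - t[0])) < 1e-2
        assert abs((w[-1] - w[-2]) / (t[1] - t[0])) < 1e-2


class TestFitting:
    def test_identity_pairs_give_identity_map(self):
        pts = grid_points(5, 0, 50, jitter_seed=1)
        t = fit_lwm(ControlPointPairs(pts, pts.copy()))
        query = grid_points(7, 5, 45, jitter_seed=2)
        np.testing.assert_allclose(apply_lwm(t, query), query, atol=1e-9)

    def test_affine_pairs_reproduced_exactly(self):
        A = np.array([[2.0, 0.9, 0.1], [-1.0, -0.05, 1.1]])
        pts = grid_points(5, 0, 60, jitter_seed=3)
        fixed = np.column_stack([np.ones(len(pts)), pts]) @ A.T
        t = fit_lwm(ControlPointPairs(pts, fixed))
        query = grid_points(9, 3, 57, jitter_seed=4)
        expected = np.column_stack([np.ones(len(query)), query]) @ A.T
        np.testing.assert_allclose(apply_lwm(t, query), expected, atol=1e-8)

    def test_fewer_than_six_pairs_rejected(self):
        pts = grid_points(3)[:5]
        with pytest.raises(TransformError, match="6"):
            ControlPointPairs(pts, pts.copy())

    def test_collinear_neighborhood_names_point(self):
        x = np.linspace(0, 50, 8)
        pts = np.column_stack([x, 2.0 * x])  # all on one line
        with pytest.raises(TransformError, match="control point 0"):
            fit_lwm(ControlPointPairs(pts, pts.copy()), n_neighbors=8)

    def test_duplicate_fixed_points_rejected(self):
        pts = grid_points(3)
        fixed = pts.copy()
        fixed[1] = fixed[0]
        with pytest.raises(TransformError, match="duplicated"):
            ControlPointPairs(pts, fixed)


class TestQuadraticExactness:
    """Central oracle: degree-2 data is reproduced everywhere covered."""

    @pytest.mark.parametrize("seed", range(5))
    def test_global_quadratic_reproduced(self, seed):
        coeffs = random_quadratic(seed)
        moving = grid_points(7, 0, 100, jitter_seed=seed + 100)
        pairs = ControlPointPairs(moving, poly2_eval(coeffs, moving))
        t = fit_lwm(pairs, n_neighbors=16)
        query = grid_points(15, 2, 98)
        np.testing.assert_allclose(
            apply_lwm(t, query), poly2_eval(coeffs, query), atol=1e-6
        )

    def test_control_points_mapped_to_their_pairs(self):
        coeffs = random_quadratic(42)
        moving = grid_points(6, 0, 80, jitter_seed=5)
        pairs = ControlPointPairs(moving, poly2_eval(coeffs, moving))
        t = fit_lwm(pairs)
        np.testing.assert_allclose(apply_lwm(t, moving), pairs.fixed, atol=1e-8)

    def test_jittered_pairs_held_out_error_below_jitter(self):
        """Noise on the pairs does not amplify: held-out RMS < jitter."""
        rng = np.random.default_rng(9)
        coeffs = random_quadratic(7)
        moving = grid_points(9, 0, 100, jitter_seed=8)
        jitter = 0.5
        fixed = poly2_eval(coeffs, moving) + rng.normal(0, jitter, (len(moving), 2))
        t = fit_lwm(ControlPointPairs(moving, fixed))
        held_out = grid_points(13, 5, 95)
        err = apply_lwm(t, held_out) - poly2_eval(coeffs, held_out)
        assert np.sqrt((err**2).sum(1).mean()) < 2 * jitter

    def test_forward_inverse_compose_to_identity(self):
        coeffs = random_quadratic(3)
        moving = grid_points(9, 0, 100, jitter_seed=10)
        pairs = ControlPointPairs(moving, poly2_eval(coeffs, moving))
        fwd = fit_lwm(pairs, direction="moving_to_fixed")
        inv = fit_lwm(pairs, direction="fixed_to_moving")
        query = grid_points(11, 10, 90)
        round_trip = apply_lwm(inv, apply_lwm(fwd, query))
        rms = np.sqrt(((round_trip - query) ** 2).sum(1).mean())
        assert rms < 0.5

    def test_fallback_for_uncovered_points_logged(self):
        pts = grid_points(3, 0, 10, jitter_seed=11)
        t = fit_lwm(ControlPointPairs(pts, pts.copy()), n_neighbors=9)
        counts = []
        out = apply_lwm(t, np.array([[500.0, 500.0]]), count_fallback=counts)
        assert counts == [1]
        assert np.all(np.isfinite(out))


class TestWarping:
    def test_identity_image_warp(self):
        rng = np.random.default_rng(12)
        img = rng.uniform(20, 35, (40, 50))
        pts = grid_points(5, 0, 45, jitter_seed=13)
        ident = fit_lwm(ControlPointPairs(pts, pts.copy()))
        warped, valid = warp_image(img, ident, (40, 50))
        np.testing.assert_allclose(warped[valid], img[valid], atol=1e-6)

    def test_pure_translation_shifts_pixels(self):
        rng = np.random.default_rng(14)
        img = rng.uniform(0, 1, (30, 40))
        pts = grid_points(5, 0, 35, jitter_seed=15)
        # inverse transform maps output coords to input coords: p -> p + (5, 0)
        shift = fit_lwm(ControlPointPairs(pts, pts + np.array([5.0, 0.0])))
        warped, valid = warp_image(img, shift, (30, 40))
        np.testing.assert_allclose(warped[:, :30][valid[:, :30]],
                                   img[:, 5:35][valid[:, :30]], atol=1e-6)
        assert not valid[:, 36:].any()  # off the right edge of the input

    def test_binary_mask_stays_binary(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:18, 12:20] = True
        pts = grid_points(5, 0, 29, jitter_seed=16)
        ident = fit_lwm(ControlPointPairs(pts, pts.copy()))
        warped, _ = warp_image(mask, ident, (30, 30), interpolation="nearest")
        assert warped.dtype == bool
        assert set(np.unique(warped)) <= {False, True}

    def test_polygon_affine_maps_vertices(self):
        A = np.array([[1.0, 0.8, 0.0], [2.0, 0.0, 0.8]])
        coeffs = np.hstack([A, np.zeros((2, 3))])
        pts = grid_points(6, 0, 60, jitter_seed=17)
        t = fit_lwm(ControlPointPairs(pts, poly2_eval(coeffs, pts)))
        tri = np.array([[10.0, 10.0], [40.0, 12.0], [25.0, 45.0]])
        mapped = warp_polygon(t, tri)
        expected = poly2_eval(coeffs, tri)
        # original vertices appear among the densified outputs
        for v in expected:
            assert np.min(np.linalg.norm(mapped - v, axis=1)) < 1e-6
        seg = np.linalg.norm(np.diff(np.vstack([mapped, mapped[:1]]), axis=0), axis=1)
        assert seg.max() <= 1.0 + 1e-9

    def test_densified_polygon_area_matches_dense_truth(self):
        from irtbat.roi import rasterize_polygon

        coeffs = random_quadratic(19)
        pts = grid_points(7, 0, 100, jitter_seed=18)
        t = fit_lwm(ControlPointPairs(pts, poly2_eval(coeffs, pts)))
        square = np.array([[20.0, 20.0], [80.0, 20.0], [80.0, 80.0], [20.0, 80.0]])
        mapped = warp_polygon(t, square)
        mask = rasterize_polygon(mapped, (160, 160))
        # high-density truth: map a finely sampled boundary through the
        # closed-form quadratic itself
        dense = []
        for i in range(4):
            a, b = square[i], square[(i + 1) % 4]
            frac = np.linspace(0, 1, 400, endpoint=False)
            dense.append(a + frac[:, None] * (b - a))
        truth_poly = poly2_eval(coeffs, np.vstack(dense))
        truth_mask = rasterize_polygon(truth_poly, (160, 160))
        sym_diff = np.logical_xor(mask, truth_mask).sum()
        assert sym_diff <= 0.02 * truth_mask.sum()

    def test_serialization_round_trip(self, tmp_path):
        pts = grid_points(5, 0, 40, jitter_seed=20)
        t = fit_lwm(ControlPointPairs(pts, pts * 1.1))
        path = t.to_json(tmp_path / "t.json")
        back = LwmTransform.from_json(path)
        query = grid_points(6, 5, 35)
        np.testing.assert_allclose(apply_lwm(back, query), apply_lwm(t, query))
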