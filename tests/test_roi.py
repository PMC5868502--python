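"""Neck-contour detection, ROI polygon rasterization, reference circle."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from irtbat.errors import ContrastError, GeometryError
from irtbat.radiometric import TemperatureFrame
from irtbat.roi import (
    ApexSet,
    ContourParams,
    NeckContour,
    build_reference_region,
    build_roi_mask,
    detect_neck_contour,
    rasterize_polygon,
)


class TestContour:
    def test_straight_edge_found_exactly(self, step_edge_frame, edge_apices):
        contour = detect_neck_contour(step_edge_frame, edge_apices, "right",
                                      ContourParams(subpixel=False))
        # gradient magnitude peaks astride the step; both columns 39/40 border it
        assert np.all(np.abs(contour.xs - 40.0) <= 1.0)
        assert contour.ys[0] == 10 and contour.ys[-1] == 40

    def test_slanted_blurred_noisy_edge_recovered(self):
        """≤ 1 px RMS on a blurred, noisy slanted edge with known position."""
        rng = np.random.default_rng(7)
        rows, cols = 60, 100
        yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
        true_x = 40.0 + 0.2 * (yy[:, 0] - 10.0)
        temp = np.where(xx < true_x[:, None], 34.0, 22.0).astype(float)
        temp = gaussian_filter(temp, 1.0) + rng.normal(0, 0.1, temp.shape)
        frame = TemperatureFrame(temp_c=temp, timestamp=0.0)
        apices = ApexSet(
            superolateral_left=(5.0, 10.0), superolateral_right=(40.0, 10.0),
            acromioclavicular_left=(3.0, 40.0), acromioclavicular_right=(46.0, 40.0),
            sternal=(20.0, 45.0), frame_shape=(rows, cols),
        )
        contour = detect_neck_contour(frame, apices, "right")
        interior = slice(1, -1)  # endpoints are pinned to the apices
        err = contour.xs[interior] - true_x[contour.ys[interior]]
        assert np.sqrt(np.mean(err**2)) <= 1.0

    def test_uniform_frame_raises_insufficient_contrast(self, edge_apices):
        frame = TemperatureFrame(temp_c=np.full((60, 100), 30.0), timestamp=0.0)
        with pytest.raises(ContrastError, match="insufficient contrast"):
            detect_neck_contour(frame, edge_apices, "right")

    def test_invariant_to_constant_offset(self, step_edge_frame, edge_apices):
        shifted = TemperatureFrame(temp_c=step_edge_frame.temp_c + 7.0, timestamp=0.0)
        c1 = detect_neck_contour(step_edge_frame, edge_apices, "right")
        c2 = detect_neck_contour(shifted, edge_apices, "right")
        np.testing.assert_array_equal(c1.xs, c2.xs)


class TestRoiMask:
    def test_triangle_area_matches_geometry(self):
        """Right triangle with legs 30 and 40 px rasterizes to ~600 px.

        Vertices sit off the pixel grid, as clicked apices do in practice;
        the half-coverage rule then tracks the geometric area closely.
        """
        apices = ApexSet(
            superolateral_left=(5.0, 10.45), superolateral_right=(40.45, 10.45),
            acromioclavicular_left=(3.0, 50.45), acromioclavicular_right=(40.45, 50.45),
            sternal=(10.45, 50.45), frame_shape=(80, 80),
        )
        ys = np.arange(10, 51)
        contour = NeckContour(xs=np.full(len(ys), 40.45), ys=ys, side="right")
        mask = build_roi_mask(apices, contour, (80, 80))
        assert abs(mask.area_px - 600) <= 0.02 * 600

    def test_degenerate_collinear_polygon_rejected(self):
        """Collinear vertices span zero area → empty-mask geometry error."""
        collinear = np.array([[10.0, 10.0], [20.0, 20.0], [30.0, 30.0], [40.0, 40.0]])
        with pytest.raises(GeometryError, match="degenerate|invalid"):
            rasterize_polygon(collinear, (80, 80))

    def test_contour_endpoints_must_match_apices(self):
        apices = ApexSet(
            superolateral_left=(5.0, 10.0), superolateral_right=(40.0, 10.0),
            acromioclavicular_left=(3.0, 50.0), acromioclavicular_right=(40.0, 50.0),
            sternal=(20.0, 55.0), frame_shape=(80, 80),
        )
        ys = np.arange(10, 51)
        contour = NeckContour(xs=np.full(len(ys), 60.0), ys=ys, side="right")
        with pytest.raises(GeometryError, match="endpoints"):
            build_roi_mask(apices, contour, (80, 80))

    def test_mirror_symmetric_apices_give_mirror_masks(self, spec):
        """Left/right masks from a symmetric scene are mirror images."""
        apices = spec.apices()
        dims = spec.shape
        left = build_roi_mask(apices, spec.true_contour("left"), dims)
        right = build_roi_mask(apices, spec.true_contour("right"), dims)
        cols = dims[1]
        # the phantom is symmetric about x = cx = (cols/2); reflect and compare
        assert spec.cx * 2 == cols
        reflected = right.mask[:, ::-1]
        # reflection about pixel grid center maps x -> cols-1-x, i.e. symmetry
        # axis cx - 0.5; shift by one column to land on the cx axis
        reflected = np.roll(reflected, 1, axis=1)
        mismatch = np.logical_xor(reflected, left.mask).sum()
        assert mismatch == 0

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]])
        with pytest.raises(GeometryError, match="self-intersecting|invalid"):
            rasterize_polygon(bowtie, (20, 20))

    def test_rasterization_center_rule_oracle(self):
        """Strictly interior pixel centers are in; clearly exterior ones are out."""
        rng = np.random.default_rng(3)
        from shapely.geometry import Point, Polygon

        for _ in range(5):
            pts = rng.uniform(5, 45, size=(3, 2))
            poly = Polygon(pts)
            if poly.area < 50:
                continue
            mask = rasterize_polygon(pts, (50, 50))
            yy, xx = np.mgrid[0:50, 0:50]
            for y, x in zip(yy.ravel()[::7], xx.ravel()[::7]):
                d = poly.boundary.distance(Point(x, y))
                if d > 0.8:
                    assert mask[y, x] == poly.contains(Point(x, y))


class TestReferenceRegion:
    def test_circle_pixel_count_is_81(self):
        """10-px-diameter circle at integer center: brute-force dx²+dy²≤25."""
        apices = ApexSet(
            superolateral_left=(20.0, 10.0), superolateral_right=(80.0, 10.0),
            acromioclavicular_left=(15.0, 40.0), acromioclavicular_right=(85.0, 40.0),
            sternal=(50.0, 50.0), frame_shape=(120, 120),
        )
        ref = build_reference_region(apices, (120, 120), offset_px=10.0)
        assert ref.center == (50.0, 60.0)
        brute = sum(
            1 for dx in range(-6, 7) for dy in range(-6, 7) if dx * dx + dy * dy <= 25
        )
        assert brute == 81
        assert ref.mask.sum() == brute

    def test_zero_offset_centers_on_sternal_apex(self):
        apices = ApexSet(
            superolateral_left=(20.0, 10.0), superolateral_right=(80.0, 10.0),
            acromioclavicular_left=(15.0, 40.0), acromioclavicular_right=(85.0, 40.0),
            sternal=(50.0, 50.0), frame_shape=(120, 120),
        )
        ref = build_reference_region(apices, (120, 120), offset_px=0.0)
        assert ref.center == apices.sternal

    def test_circle_overflowing_frame_rejected(self):
        apices = ApexSet(
            superolateral_left=(20.0, 10.0), superolateral_right=(80.0, 10.0),
            acromioclavicular_left=(15.0, 40.0), acromioclavicular_right=(85.0, 40.0),
            sternal=(50.0, 55.0), frame_shape=(60, 120),
        )
        with pytest.raises(GeometryError, match="does not fit"):
            build_reference_region(apices, (60, 120), offset_px=10.0)


def test_roi_and_reference_disjoint_on_phantom(spec):
    apices = spec.apices()
    ref = build_reference_region(apices, spec.shape, offset_px=spec.reference_offset_px)
    for side in ("left", "right"):
        roi = build_roi_mask(apices, spec.true_contour(side), spec.shape)
        assert not np.any(roi.mask & ref.mask)


def test_apex_invariants_enforced():
    with pytest.raises(GeometryError, match="between"):
        ApexSet(
            superolateral_left=(60.0, 10.0), superolateral_right=(80.0, 10.0),
            acromioclavicular_left=(55.0, 40.0), acromioclavicular_right=(85.0, 40.0),
            sternal=(50.0, 50.0),
        )
    with pytest.raises(GeometryError, match="above"):
        ApexSet(
            superolateral_left=(20.0, 45.0), superolateral_right=(80.0, 10.0),
            acromioclavicular_left=(15.0, 40.0), acromioclavicular_right=(85.0, 40.0),
            sternal=(50.0, 50.0),
        )
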