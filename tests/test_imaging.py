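"""Calibration, segmentation and 2-D lesion metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pfaquant as pq
from pfaquant.errors import GeometryError, MetricError
from pfaquant.imaging import stained_pixels
from pfaquant.synth import RenderSpec, make_parametric_lesion, render_views


def flat_calibration(mpp: float = 0.1) -> pq.ImageCalibration:
    return pq.ImageCalibration((0.0, 0.0), (100.0, 0.0), 100.0 * mpp, mpp)


def mask_from_bool(arr, mpp=0.1, view="top") -> pq.LesionMask:
    return pq.LesionMask(view, np.asarray(arr, bool), 120, flat_calibration(mpp))


class TestCalibration:
    def test_horizontal_scale(self):
        cal = pq.calibrate(None, (0, 0), (100, 0), 10.0)
        assert cal.mm_per_pixel == pytest.approx(0.1)

    def test_345_triangle(self):
        cal = pq.calibrate(None, (0, 0), (3, 4), 1.0)
        assert cal.mm_per_pixel == pytest.approx(0.2)

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            pq.calibrate(None, (5, 5), (5, 5), 1.0)

    def test_scale_bar_fixture_recovers_renderer_scale(self):
        lesion = make_parametric_lesion("half_ellipsoid", {"a": 3, "b": 2, "c": 1.5})
        spec = RenderSpec(noise_sigma=0.0, seed=0)
        top, _, sidecar = render_views(lesion, spec)
        bar = np.asarray(sidecar["render"]["scale_bar_px"], float)
        cal = pq.calibrate(np.asarray(top), bar[0], bar[1],
                           sidecar["render"]["scale_bar_mm"])
        assert cal.mm_per_pixel == pytest.approx(spec.mm_per_pixel, rel=0.01)


class TestSegmentation:
    def test_all_white_image_gives_empty_mask_with_warning(self):
        img = np.full((50, 50), 255, np.uint8)
        with pytest.warns(UserWarning):
            m = pq.segment_stained(img, 128, flat_calibration())
        assert m.empty_warning
        assert pq.measure_area(m) == 0.0

    def test_constructed_pixel_count_is_exact(self):
        img = np.full((64, 64), 220, np.uint8)
        rr = np.array([5, 5, 6, 10, 20, 33, 33])
        cc = np.array([7, 8, 7, 40, 21, 50, 51])
        img[rr, cc] = 40
        # all dark pixels form specks except none dominate: use one blob
        img[:] = 220
        img[10:15, 10:20] = 40  # k = 50 contiguous pixels
        m = pq.segment_stained(img, 128, flat_calibration())
        assert int(m.mask.sum()) == 50

    def test_speck_components_removed_lobes_kept(self):
        img = np.full((80, 80), 220, np.uint8)
        img[10:30, 10:30] = 40    # lobe 1: 400 px
        img[10:30, 50:70] = 40    # lobe 2: 400 px
        img[70, 70] = 40          # speck
        m = pq.segment_stained(img, 128, flat_calibration())
        assert int(m.mask.sum()) == 800

    def test_holes_filled(self):
        img = np.full((60, 60), 220, np.uint8)
        img[20:40, 20:40] = 40
        img[28:32, 28:32] = 220  # glare hole
        m = pq.segment_stained(img, 128, flat_calibration())
        assert int(m.mask.sum()) == 400

    def test_dice_against_render_truth_with_noise(self):
        import matplotlib.path as mpath

        lesion = make_parametric_lesion("half_ellipsoid", {"a": 3, "b": 2, "c": 1.5})
        spec = RenderSpec(noise_sigma=8.0, seed=3)
        top, _, sidecar = render_views(lesion, spec)
        img = np.asarray(top)
        mpp = spec.mm_per_pixel
        x0, y0 = sidecar["render"]["top_origin_mm"]
        ny, nx = img.shape[:2]
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny))
        pts_mm = np.column_stack([(X.ravel() + 0.5) * mpp + x0,
                                  (Y.ravel() + 0.5) * mpp + y0])
        truth = mpath.Path(np.asarray(sidecar["top_polygons_mm"][0])) \
            .contains_points(pts_mm).reshape(ny, nx)
        m = pq.segment_stained(img, 120, flat_calibration(mpp))
        inter = (m.mask & truth).sum()
        dice = 2 * inter / (m.mask.sum() + truth.sum())
        assert dice >= 0.95

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 9999),
           t1=st.integers(0, 255), t2=st.integers(0, 255))
    def test_threshold_monotonicity(self, seed, t1, t2):
        """Raising the threshold never shrinks the raw stained set."""
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        lo, hi = sorted((t1, t2))
        assert np.all(stained_pixels(img, lo) <= stained_pixels(img, hi))


class TestAreaLengthWidth:
    def test_area_is_count_times_pixel_area(self):
        m = mask_from_bool(np.ones((100, 100)), mpp=0.05)
        assert pq.measure_area(m) == pytest.approx(10_000 * 0.05**2)  # 25 mm^2

    def test_single_pixel_measures_one_pixel(self):
        arr = np.zeros((10, 10), bool)
        arr[5, 5] = True
        m = mask_from_bool(arr, mpp=0.1)
        assert pq.measure_length_width(m) == (pytest.approx(0.1), pytest.approx(0.1))

    def test_empty_mask_raises(self):
        with pytest.raises(MetricError):
            pq.measure_length_width(mask_from_bool(np.zeros((5, 5))))

    def test_rectangle_against_orientation_bruteforce(self):
        arr = np.zeros((60, 80), bool)
        arr[10:30, 10:50] = True  # 20 rows x 40 cols
        m = mask_from_bool(arr, mpp=0.1)
        length, width = pq.measure_length_width(m)
        # independent oracle: scan all orientations over pixel centres
        ys, xs = np.nonzero(arr)
        pts = np.column_stack([xs, ys]).astype(float)
        best_len, best_theta = 0.0, 0.0
        for theta in np.linspace(0, np.pi, 3601):
            d = np.array([np.cos(theta), np.sin(theta)])
            proj = pts @ d
            ext = proj.max() - proj.min()
            if ext > best_len:
                best_len, best_theta = ext, theta
        n = np.array([-np.sin(best_theta), np.cos(best_theta)])
        perp_ext = (pts @ n).max() - (pts @ n).min()
        assert length == pytest.approx((best_len + 1) * 0.1, rel=1e-3)
        assert width == pytest.approx((perp_ext + 1) * 0.1, rel=5e-3)
        assert width <= length

    def test_ellipse_fixture_metrics(self):
        lesion = make_parametric_lesion("half_ellipsoid", {"a": 3, "b": 2, "c": 1})
        spec = RenderSpec(noise_sigma=0.0, seed=0)
        top, _, _ = render_views(lesion, spec)
        m = pq.segment_stained(np.asarray(top), 120, flat_calibration(spec.mm_per_pixel))
        assert pq.measure_area(m) == pytest.approx(np.pi * 3 * 2, rel=0.02)
        length, width = pq.measure_length_width(m)
        assert length == pytest.approx(6.0, rel=0.03)
        assert width == pytest.approx(4.0, rel=0.03)

    def test_rotation_robustness(self):
        from skimage.transform import rotate

        lesion = make_parametric_lesion("half_ellipsoid", {"a": 3, "b": 2, "c": 1})
        spec = RenderSpec(noise_sigma=0.0, seed=0)
        top, _, _ = render_views(lesion, spec)
        img = np.asarray(top)[:, :, 0].astype(float)
        cal = flat_calibration(spec.mm_per_pixel)
        m0 = pq.segment_stained(img, 120, cal)
        a0 = pq.measure_area(m0)
        l0, w0 = pq.measure_length_width(m0)
        rot = rotate(img, 30.0, resize=True, cval=255, preserve_range=True)
        m1 = pq.segment_stained(rot.astype(np.uint8), 120, cal)
        a1 = pq.measure_area(m1)
        l1, w1 = pq.measure_length_width(m1)
        assert a1 == pytest.approx(a0, rel=0.03)
        assert l1 == pytest.approx(l0, rel=0.03)
        assert w1 == pytest.approx(w0, rel=0.03)

    def test_downsampling_scale_equivariance(self):
        lesion = make_parametric_lesion("half_ellipsoid", {"a": 3, "b": 2, "c": 1})
        spec = RenderSpec(noise_sigma=0.0, seed=0)
        top, _, _ = render_views(lesion, spec)
        img = np.asarray(top)
        a_full = pq.measure_area(
            pq.segment_stained(img, 120, flat_calibration(spec.mm_per_pixel)))
        a_half = pq.measure_area(
            pq.segment_stained(img[::2, ::2], 120,
                               flat_calibration(2 * spec.mm_per_pixel)))
        assert a_half == pytest.approx(a_full, rel=0.02)


def semicircle_mask(radius_px: int, pad: int = 10):
    n = 2 * radius_px + 2 * pad
    Y, X = np.mgrid[0:n, 0:n]
    cx, cy = n / 2, pad
    inside = ((X - cx) ** 2 + (Y - cy) ** 2 <= radius_px**2) & (Y >= cy)
    return inside, (cx, cy)


class TestCutPolygonAndDepth:
    def test_semicircle_depth_equals_radius(self):
        r_px = 50
        arr, (cx, cy) = semicircle_mask(r_px)
        m = mask_from_bool(arr, mpp=0.1, view="cut")
        poly = pq.trace_cut_polygon(m, [(cx - r_px, cy), (cx + r_px, cy)])
        depth = pq.measure_depth(poly)
        assert depth == pytest.approx(r_px * 0.1, rel=0.02)

    def test_rectangle_depth_equals_height(self):
        arr = np.zeros((80, 80), bool)
        arr[10:50, 20:60] = True  # 40 px tall, top at row 10
        m = mask_from_bool(arr, mpp=0.1, view="cut")
        poly = pq.trace_cut_polygon(m, [(20, 10), (59, 10)])
        assert pq.measure_depth(poly) == pytest.approx(4.0, abs=0.15)

    def test_depth_invariant_under_translation(self):
        arr = np.zeros((100, 100), bool)
        arr[10:50, 20:60] = True
        m = mask_from_bool(arr, mpp=0.1, view="cut")
        d0 = pq.measure_depth(pq.trace_cut_polygon(m, [(20, 10), (59, 10)]))
        shifted = np.roll(np.roll(arr, 17, axis=1), 5, axis=0)
        m2 = mask_from_bool(shifted, mpp=0.1, view="cut")
        d1 = pq.measure_depth(pq.trace_cut_polygon(m2, [(37, 15), (76, 15)]))
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_traced_polygon_close_to_truth_boundary(self):
        from shapely.geometry import Polygon

        r_px = 60
        arr, (cx, cy) = semicircle_mask(r_px)
        m = mask_from_bool(arr, mpp=0.1, view="cut")
        poly = pq.trace_cut_polygon(m, [(cx - r_px, cy), (cx + r_px, cy)])
        # truth semicircle in the same mm frame
        t = np.linspace(0, np.pi, 200)
        truth = np.column_stack([cx + r_px * np.cos(t), cy + r_px * np.sin(t)]) * 0.1
        truth = np.vstack([truth, truth[:1]])
        hd = Polygon(poly.vertices).exterior.hausdorff_distance(
            Polygon(truth).exterior)
        assert hd <= 2 * 0.1  # 2 px

    def test_zero_length_top_line_rejected(self):
        arr = np.zeros((20, 20), bool)
        arr[5:15, 5:15] = True
        m = mask_from_bool(arr, view="cut")
        with pytest.raises(GeometryError):
            pq.trace_cut_polygon(m, [(5, 5), (5, 5)])
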