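"""Lethal-threshold calibration: inversion, boundary sampling, registration."""

import numpy as np
import pytest

import pfaquant as pq
from pfaquant.errors import GeometryError, PlaneRangeError
from pfaquant.imaging import ImageCalibration, LesionMask


def mask_with_mpp(mpp: float) -> LesionMask:
    cal = ImageCalibration((0, 0), (100, 0), 100 * mpp, mpp)
    m = np.zeros((50, 50), bool)
    m[20:30, 20:30] = True
    return LesionMask("top", m, 120, cal)


class TestAreaMatch:
    @pytest.mark.parametrize("level", [15.0, 30.0, 60.0])
    def test_self_inverse_on_radial_field(self, radial_plane, level):
        area = np.pi * (100.0 / level) ** 2
        est = pq.eft_by_area_match(area, radial_plane)
        assert not est.out_of_range
        assert est.threshold_v_per_cm == pytest.approx(level, rel=0.01)

    def test_matches_superlevel_area_inverse(self, radial_plane):
        target = pq.superlevel_area(radial_plane, 42.0)
        est = pq.eft_by_area_match(target, radial_plane)
        assert pq.superlevel_area(radial_plane, est.threshold_v_per_cm) == \
            pytest.approx(target, rel=0.006)

    def test_oversized_lesion_flagged_not_silent(self):
        # weak radial field: the 1 V/cm superlevel set is a disc well inside
        # the plane, so a larger lesion area is out of the attainable range
        u = np.linspace(-10, 10, 201)
        U, V = np.meshgrid(u, u, indexing="ij")
        R = np.sqrt(U**2 + V**2)
        R[R < 1e-9] = 1e-9
        plane = pq.FieldPlane(values=5.0 / R, u=u, v=u, axes=("x", "y"),
                              plane_axis="z", offset=0.0)
        a_lo = pq.superlevel_area(plane, 1.0)
        est = pq.eft_by_area_match(min(a_lo * 1.5, plane.extent_area), plane)
        assert est.out_of_range

    def test_lesion_larger_than_plane_rejected(self, radial_plane):
        with pytest.raises(ValueError):
            pq.eft_by_area_match(radial_plane.extent_area * 2, radial_plane)

    def test_voltage_scaling_doubles_estimate(self, radial_plane):
        doubled = pq.FieldPlane(values=radial_plane.values * 2.0,
                                u=radial_plane.u, v=radial_plane.v,
                                axes=radial_plane.axes, plane_axis="z", offset=0.0)
        area = np.pi * (100.0 / 25.0) ** 2
        e1 = pq.eft_by_area_match(area, radial_plane).threshold_v_per_cm
        e2 = pq.eft_by_area_match(area, doubled).threshold_v_per_cm
        assert e2 == pytest.approx(2 * e1, rel=0.01)


class TestBoundaryQuantile:
    def circle(self, rho, n=200):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([rho * np.cos(t), rho * np.sin(t)])

    def test_boundary_on_isoline_returns_level_at_any_quantile(self, radial_plane):
        rho = 4.0
        b = self.circle(rho)
        for q in (0.0, 0.5, 1.0):
            est = pq.eft_by_boundary_quantile(b, radial_plane, quantile=q)
            assert est.threshold_v_per_cm == pytest.approx(100.0 / rho, rel=0.01)

    def test_jittered_boundary_median_robust(self, radial_plane):
        rng = np.random.default_rng(11)
        rho = 4.0
        b = self.circle(rho) + rng.normal(0, 0.1, (200, 2))
        est = pq.eft_by_boundary_quantile(b, radial_plane)
        assert est.threshold_v_per_cm == pytest.approx(100.0 / rho, rel=0.05)
        assert est.residual > 0  # IQR reflects the jitter

    def test_out_of_domain_vertices_reported(self, radial_plane):
        b = self.circle(50.0)
        with pytest.raises(PlaneRangeError):
            pq.eft_by_boundary_quantile(b, radial_plane)

    def test_method_concordance_on_noiseless_lesion(self, radial_plane):
        rho = 3.0
        area = np.pi * rho**2
        e_area = pq.eft_by_area_match(area, radial_plane).threshold_v_per_cm
        e_bnd = pq.eft_by_boundary_quantile(self.circle(rho),
                                            radial_plane).threshold_v_per_cm
        assert e_area == pytest.approx(e_bnd, rel=0.03)


class TestRegistration:
    def test_marks_at_scene_positions_give_identity(self, paper_config):
        mpp = 0.05
        mask = mask_with_mpp(mpp)
        s = paper_config.geometry.electrode_center_distance / 2
        marks = np.array([[-s / mpp, 0.0], [s / mpp, 0.0]])
        reg = pq.register_lesion(mask, marks, paper_config)
        assert reg.residual_mm < 1e-9
        pts = reg.apply_px(marks)
        assert np.allclose(pts, [[-s, 0], [s, 0]], atol=1e-9)

    def test_swapped_marks_are_a_rotation_with_same_residual(self, paper_config):
        mpp = 0.05
        mask = mask_with_mpp(mpp)
        s = paper_config.geometry.electrode_center_distance / 2
        marks = np.array([[s / mpp, 0.0], [-s / mpp, 0.0]])
        reg = pq.register_lesion(mask, marks, paper_config)
        assert reg.residual_mm < 1e-9  # symmetric scene: order irrelevant
        assert np.allclose(reg.rotation, [[-1, 0], [0, -1]], atol=1e-12)

    def test_known_transform_recovered(self, paper_config):
        rng = np.random.default_rng(5)
        mpp = 0.05
        mask = mask_with_mpp(mpp)
        s = paper_config.geometry.electrode_center_distance / 2
        theta = np.deg2rad(25.0)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        t = np.array([3.1, -2.2])
        scene_marks = np.array([[-s, 0.0], [s, 0.0]])
        img_marks_mm = scene_marks @ R.T + t
        reg = pq.register_lesion(mask, img_marks_mm / mpp, paper_config)
        assert reg.residual_mm <= 0.1
        # a probe transported through image->scene lands at its scene position
        probe_scene = rng.uniform(-2, 2, (5, 2))
        probe_img = probe_scene @ R.T + t
        assert np.allclose(reg.apply_px(probe_img / mpp), probe_scene, atol=0.1)

    def test_close_marks_rejected(self, paper_config):
        mask = mask_with_mpp(0.05)
        with pytest.raises(GeometryError):
            pq.register_lesion(mask, np.array([[0, 0], [5, 0]]), paper_config)


class TestBatchReport:
    def test_single_estimate_sem_undefined(self):
        est = pq.EFTEstimate(240.0, "area_match", condition="300V")
        out = pq.eft_batch_report([est])
        assert out.loc[0, "mean"] == 240.0
        assert not out.loc[0, "sem_defined"]

    def test_identical_estimates_have_zero_sem(self):
        ests = [pq.EFTEstimate(200.0, "area_match", condition="c")] * 4
        out = pq.eft_batch_report(ests)
        assert out.loc[0, "sem"] == pytest.approx(0.0)

    def test_seeded_spread_matches_closed_form(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(240, 20, 10)
        ests = [pq.EFTEstimate(v, "area_match", condition="c") for v in vals]
        out = pq.eft_batch_report(ests)
        assert out.loc[0, "mean"] == pytest.approx(vals.mean())
        assert out.loc[0, "sem"] == pytest.approx(vals.std(ddof=1) / np.sqrt(10))

    def test_mixed_conditions_require_explicit_opt_in(self):
        ests = [pq.EFTEstimate(200.0, "area_match", condition="a"),
                pq.EFTEstimate(210.0, "area_match", condition="b")]
        with pytest.raises(ValueError):
            pq.eft_batch_report(ests)
        out = pq.eft_batch_report(ests, allow_mixed_conditions=True)
        assert len(out) == 2
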