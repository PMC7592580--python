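"""Scan pipeline: quality gating, axis recovery, slicing, volume accuracy."""
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import limbvol as lv
from limbvol.errors import AxisEstimationError, SliceSkippedError
from limbvol.scan_pipeline import QualityConfig, estimate_axis, slice_circumference


def _circle_points(radius, n, z=0.0, rng=None):
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        (radius * np.cos(theta), radius * np.sin(theta), np.full(n, z))
    )
    return pts


class TestQualityGate:
    def test_dense_clean_scan_is_ok(self, dense_cylinder_scan):
        _, scan = dense_cylinder_scan
        verdict = lv.assess_quality(scan)
        assert verdict.ok and verdict.reasons == ()

    def test_clothing_occlusion_reports_coverage_gap(self):
        limb = lv.make_limb(40.0, 4.0, seed=3)
        spec = lv.NoiseSpec(points_per_view=12500, occlusion_fraction=0.5)
        scan = lv.sample_point_cloud(limb, spec)
        verdict = lv.assess_quality(scan)
        assert not verdict.ok
        assert "coverage-gap" in verdict.reasons

    def test_tiny_cloud_reports_too_few_points(self):
        limb = lv.make_limb(40.0, 4.0, seed=3)
        scan = lv.sample_point_cloud(limb, lv.NoiseSpec(points_per_view=25))
        verdict = lv.assess_quality(scan)
        assert not verdict.ok
        assert "too-few-points" in verdict.reasons

    def test_low_quality_scan_yields_no_volume(self):
        limb = lv.make_limb(40.0, 4.0, seed=3)
        spec = lv.NoiseSpec(points_per_view=12500, occlusion_fraction=0.4)
        scan = lv.sample_point_cloud(limb, spec)
        result = lv.scan_limb_volume(scan)
        assert result.quality == "low_quality"
        assert result.total_volume_ml is None
        assert result.reasons


class TestAxisEstimation:
    def test_symmetric_cylinder_axis_is_exactly_z(self):
        """An azimuthally symmetric cylinder cloud has principal axis +z."""
        pts = np.vstack([_circle_points(4.0, 360, z=z) for z in np.linspace(0, 40, 81)])
        scan = lv.LimbScan(
            points=pts,
            view_labels=np.zeros(pts.shape[0], dtype=int),
            wrist_landmark=[0, 0, 0],
            axilla_landmark=[0, 0, 40],
        )
        axis = estimate_axis(scan)
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-6)

    def test_sampled_cylinder_axis_near_z(self, dense_cylinder_scan):
        _, scan = dense_cylinder_scan
        axis = estimate_axis(scan)
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=5e-3)

    def test_rotation_equivariance(self, dense_cylinder_scan):
        _, scan = dense_cylinder_scan
        R = Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix()
        axis = estimate_axis(scan)
        rotated_axis = estimate_axis(scan.transformed(R, np.array([1.0, -2.0, 3.0])))
        np.testing.assert_allclose(rotated_axis.direction, R @ axis.direction, atol=1e-6)

    def test_noisy_taper_axis_within_one_degree(self, taper_limb):
        spec = lv.NoiseSpec(points_per_view=8000, surface_sigma_cm=0.05)
        scan = lv.sample_point_cloud(taper_limb, spec)
        axis = estimate_axis(scan)
        angle = math.degrees(math.acos(float(np.clip(axis.direction @ [0, 0, 1], -1, 1))))
        assert angle < 1.0

    def test_degenerate_cloud_rejected(self):
        pts = np.tile([1.0, 0.0, 0.0], (50, 1))
        scan = lv.LimbScan(
            points=pts,
            view_labels=np.zeros(50, dtype=int),
            wrist_landmark=[0, 0, 0],
            axilla_landmark=[0, 0, 10],
        )
        with pytest.raises(AxisEstimationError):
            estimate_axis(scan)


class TestSliceCircumference:
    def test_unit_circle_perimeter_from_below(self):
        pts = _circle_points(1.0, 1000)
        prof = slice_circumference(pts, np.zeros(3), np.array([0, 0, 1.0]), 0.0)
        assert prof.circumference_cm < 2 * math.pi
        assert prof.circumference_cm == pytest.approx(2 * math.pi, rel=1e-3)

    def test_circle_r4_within_half_percent(self):
        pts = _circle_points(4.0, 500)
        prof = slice_circumference(pts, np.zeros(3), np.array([0, 0, 1.0]), 0.0)
        assert prof.circumference_cm == pytest.approx(8 * math.pi, rel=5e-3)

    def test_three_points_give_triangle_perimeter(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        prof = slice_circumference(pts, np.zeros(3), np.array([0, 0, 1.0]), 0.0)
        assert prof.circumference_cm == pytest.approx(2 + math.sqrt(2), rel=1e-12)

    def test_too_few_points_raise_skip_signal(self):
        with pytest.raises(SliceSkippedError):
            slice_circumference(
                np.array([[0.0, 0, 0], [1, 0, 0]]),
                np.zeros(3),
                np.array([0, 0, 1.0]),
                0.0,
            )

    def test_isoperimetric_bound(self, rng):
        # noisy annulus: hull/polygon area can never beat the circle of equal perimeter
        for _ in range(10):
            n = int(rng.integers(100, 2000))
            theta = rng.uniform(0, 2 * np.pi, n)
            r = 3.0 + rng.normal(0, 0.05, n)
            pts = np.column_stack(
                (r * np.cos(theta), r * np.sin(theta), rng.uniform(-0.5, 0.5, n))
            )
            prof = slice_circumference(pts, np.zeros(3), np.array([0, 0, 1.0]), 0.0)
            assert prof.area_cm2 <= prof.circumference_cm**2 / (4 * math.pi) * 1.001


class TestScanLimbVolume:
    def test_cylinder_recovery_within_one_percent(self, dense_cylinder_scan):
        limb, scan = dense_cylinder_scan
        result = lv.scan_limb_volume(scan)
        truth = limb.analytic_volume()
        assert result.total_volume_ml == pytest.approx(truth, rel=0.01)
        # inscribed-polygon estimator under-measures convex sections
        assert result.total_volume_ml <= truth

    def test_taper_recovery_within_one_percent(self, taper_limb):
        scan = lv.sample_point_cloud(taper_limb, lv.NoiseSpec(points_per_view=12500))
        result = lv.scan_limb_volume(scan)
        truth = taper_limb.analytic_volume()
        assert result.total_volume_ml == pytest.approx(truth, rel=0.01)
        assert result.total_volume_ml <= truth

    def test_hand_blob_is_spared(self, arm_limb):
        spec = lv.NoiseSpec(points_per_view=12500)
        plain = lv.scan_limb_volume(lv.sample_point_cloud(arm_limb, spec))
        with_hand = lv.scan_limb_volume(
            lv.sample_point_cloud(arm_limb, spec, include_hand=True)
        )
        assert with_hand.total_volume_ml == pytest.approx(
            plain.total_volume_ml, rel=2e-3
        )

    def test_rigid_motion_invariance(self, arm_limb):
        scan = lv.sample_point_cloud(arm_limb, lv.NoiseSpec(points_per_view=12500))
        base = lv.scan_limb_volume(scan).total_volume_ml
        R = Rotation.from_euler("xyz", [17, -33, 58], degrees=True).as_matrix()
        moved = scan.transformed(R, np.array([5.0, -2.0, 9.0]))
        assert lv.scan_limb_volume(moved).total_volume_ml == pytest.approx(
            base, rel=1e-3
        )

    def test_scan_agrees_with_tape_and_sits_below(self, arm_limb):
        """Same limb, both modalities: within 1%, scan <= tape (inscribed bias)."""
        tape = lv.tape_limb_volume(lv.simulate_tape_series(arm_limb)).total_volume_ml
        scan = lv.scan_limb_volume(
            lv.sample_point_cloud(arm_limb, lv.NoiseSpec(points_per_view=12500))
        ).total_volume_ml
        assert scan == pytest.approx(tape, rel=0.01)
        assert scan <= tape

    def test_volume_strictly_increases_with_swelling(self):
        volumes = []
        for gamma in (1.0, 1.05, 1.1, 1.2):
            limb = lv.make_limb(
                40.0,
                [(0.0, 2.5), (15.0, 4.0), (22.0, 4.5), (40.0, 5.0)],
                swelling_factor=gamma,
                seed=7,
            )
            scan = lv.sample_point_cloud(limb, lv.NoiseSpec(points_per_view=6000))
            volumes.append(lv.scan_limb_volume(scan).total_volume_ml)
        assert all(a < b for a, b in zip(volumes, volumes[1:]))

    def test_noise_robustness_regression_guard(self, arm_limb):
        """Median |error| over 50 replicates at sigma = 0.1 cm stays under 3%."""
        truth = arm_limb.analytic_volume()
        spec = lv.NoiseSpec(points_per_view=4000, surface_sigma_cm=0.1)
        errors = []
        for replicate in range(50):
            scan = lv.sample_point_cloud(arm_limb, spec, seed=1000 + replicate)
            vol = lv.scan_limb_volume(scan).total_volume_ml
            errors.append(abs(vol - truth) / truth)
        assert float(np.median(errors)) < 0.03

    def test_partial_end_station_is_included(self):
        # 38-cm limb: final 2-cm segment retained with its true height
        limb = lv.make_limb(38.0, 3.0, seed=9)
        scan = lv.sample_point_cloud(limb, lv.NoiseSpec(points_per_view=12500))
        result = lv.scan_limb_volume(scan, include_partial_end=True)
        truth = limb.analytic_volume()
        assert result.total_volume_ml == pytest.approx(truth, rel=0.01)
        trimmed = lv.scan_limb_volume(scan, include_partial_end=False)
        assert trimmed.total_volume_ml < result.total_volume_ml

    def test_hull_area_mode_close_to_circumference_mode(self, dense_cylinder_scan):
        limb, scan = dense_cylinder_scan
        by_area = lv.scan_limb_volume(scan, area_mode="hull")
        assert by_area.total_volume_ml == pytest.approx(
            limb.analytic_volume(), rel=0.01
        )

    def test_sparse_slice_threshold_respected(self):
        limb = lv.make_limb(40.0, 4.0, seed=3)
        scan = lv.sample_point_cloud(limb, lv.NoiseSpec(points_per_view=400))
        config = QualityConfig(min_total_points=100, min_slice_points=200)
        result = lv.scan_limb_volume(scan, config=config)
        assert result.quality == "low_quality"
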