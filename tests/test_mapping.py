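"""Mapping stage: resting level, activation marker, APD80, IQR exclusion,
Bayly velocity fits, axis CV, restitution aggregation."""
from __future__ import annotations

import math
import warnings

import numpy as np
import pytest

import omkit
from omkit import (
    build_restitution,
    compute_activation_field,
    compute_apd80,
    detect_activation,
    estimate_resting_level,
    exclude_outliers_iqr,
    extract_axis_cv,
    fit_cv_bayly,
)
from omkit.mapping import activation_map_error, gaussian_kernel
from omkit.synth import WaveModel


class TestRestingLevel:
    def test_constant_trace_returns_constant(self):
        rest = estimate_resting_level(np.full((200, 3), 4.5), 977.0)
        np.testing.assert_allclose(rest, 4.5)

    def test_kernel_size_sigma7ms_truncate4(self):
        # sigma = 7 ms at 977 FPS = 6.839 samples; radius ceil(4 sigma) = 28
        k = gaussian_kernel(7.0 * 977.0 / 1000.0, truncate=4.0)
        assert k.size == 57
        assert k.sum() == pytest.approx(1.0)

    def test_trace_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            estimate_resting_level(np.zeros((40, 2)), 977.0)

    def test_noisy_resting_recovered_after_conditioning(self, small_cond):
        # conditioned + normalized beats rest at 0; the estimate must land
        # within 0.05 of that even though the raw SNR was only 0.5
        rest = estimate_resting_level(small_cond.beat.traces, 977.0)
        m = small_cond.mask.keep
        assert np.abs(rest[m]).mean() < 0.05


class TestDetectActivation:
    def test_ideal_step_at_frame_k(self):
        y = np.zeros(30)
        y[11:] = 1.0  # step occurs at frame 10 -> 11
        act, valid = detect_activation(y, frame_rate=1000.0)
        assert valid
        assert float(act) == pytest.approx(10.0)

    def test_linear_ramp_earliest_tie(self):
        y = np.zeros(40)
        y[20:30] = np.arange(1.0, 11.0)  # exactly constant unit slope
        y[30:] = 10.0
        act, _ = detect_activation(y, frame_rate=1000.0)
        assert float(act) == pytest.approx(19.0)  # first max-slope interval

    def test_flat_trace_marked_invalid(self):
        act, valid = detect_activation(np.zeros((20, 2)), 1000.0)
        assert not valid.any()
        assert np.isnan(act).all()

    def test_noiseless_movie_within_one_frame(self, noiseless_cond, noiseless_mouse):
        sc, recording, truth = noiseless_mouse
        act, valid = detect_activation(noiseless_cond.beat.traces, 977.0,
                                       smooth_ms=2.0)
        m = noiseless_cond.mask.keep & valid
        mae = activation_map_error(act, truth.activation_field, m)
        assert mae < 1000.0 / 977.0


class TestComputeAPD80:
    def test_square_pulse_duration(self):
        y = np.zeros(120)
        y[20:70] = 1.0  # 50-frame pulse
        act, _ = detect_activation(y, 1000.0)
        apd = compute_apd80(y, act, 0.0, 1000.0)
        assert float(apd) == pytest.approx(50.0, abs=1.0)

    def test_exponential_tau20_crossing_at_tau_ln5(self):
        tau = 20.0
        t = np.arange(300.0)
        y = np.where(t < 50, 0.0, np.exp(-(t - 50) / tau))
        act, _ = detect_activation(y, 1000.0)
        apd = compute_apd80(y, act, 0.0, 1000.0)
        t_cross = float(act) + float(apd)
        assert t_cross == pytest.approx(50.0 + tau * math.log(5.0), abs=0.3)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(0)
        t = np.arange(150.0)
        y = np.where(t < 20, 0.0,
                     np.where(t < 22, (t - 20) / 2.0, np.exp(-(t - 22) / 25.0)))
        y = y + 0.01 * rng.standard_normal(y.size)
        act, _ = detect_activation(y, 1000.0)
        a1 = compute_apd80(y, act, 0.0, 1000.0)
        gain, offset = 37.0, 512.0
        act2, _ = detect_activation(gain * y + offset, 1000.0)
        a2 = compute_apd80(gain * y + offset, act2, offset, 1000.0)
        assert float(a2) == pytest.approx(float(a1), abs=1e-9)

    def test_unrepolarized_pixel_flagged_nan(self):
        y = np.zeros(60)
        y[20:] = 1.0  # never comes back down
        act, _ = detect_activation(y, 1000.0)
        apd = compute_apd80(y, act, 0.0, 1000.0)
        assert np.isnan(float(apd))


class TestExcludeOutliersIQR:
    def test_worked_example(self):
        retained, bounds = exclude_outliers_iqr([10, 11, 12, 12, 13, 50])
        assert bounds == pytest.approx((9.0, 15.0))
        np.testing.assert_array_equal(sorted(retained), [10, 11, 12, 12, 13])

    def test_zero_iqr_removes_nothing(self):
        retained, bounds = exclude_outliers_iqr([5.0] * 10)
        assert retained.size == 10
        assert bounds == pytest.approx((5.0, 5.0))

    def test_fewer_than_four_unchanged(self):
        retained, bounds = exclude_outliers_iqr([1.0, 100.0, 10000.0])
        assert retained.size == 3
        assert bounds is None

    @pytest.mark.parametrize("seed", range(4))
    def test_retained_always_within_bounds(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.standard_cauchy(200) * 10 + 40
        retained, bounds = exclude_outliers_iqr(values)
        assert bounds is not None
        assert (retained >= bounds[0]).all() and (retained <= bounds[1]).all()


class TestFitCVBayly:
    def test_plane_wave_exact(self):
        v = 0.5  # mm/ms
        x = np.arange(21) * 0.1  # pixel_size 0.1 mm
        T = np.broadcast_to(x / v, (21, 21)).copy()
        field = fit_cv_bayly(T, pixel_size=0.1)
        interior = field.valid
        assert interior[3:-3, 3:-3].all()
        np.testing.assert_allclose(field.vx[interior], 100 * v, rtol=1e-6)
        np.testing.assert_allclose(field.vy[interior], 0.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_quadratic_surface_exact(self, seed):
        # the order-2 fit reproduces grad T exactly on any quadratic surface
        rng = np.random.default_rng(seed)
        c = rng.uniform(-1, 1, size=6)
        c[1:3] += np.sign(c[1:3]) * 1.0  # keep gradients well away from zero
        ps = 0.2
        yy, xx = np.mgrid[0:15, 0:15] * ps
        T = (c[0] + c[1] * xx + c[2] * yy + 0.1 * (c[3] * xx**2
             + c[4] * xx * yy + c[5] * yy**2))
        field = fit_cv_bayly(T, pixel_size=ps, residual_ms_max=np.inf)
        gx = c[1] + 0.2 * c[3] * xx + 0.1 * c[4] * yy
        gy = c[2] + 0.1 * c[4] * xx + 0.2 * c[5] * yy
        g2 = gx**2 + gy**2
        sel = field.valid
        np.testing.assert_allclose(field.vx[sel], (100 * gx / g2)[sel], rtol=1e-7)
        np.testing.assert_allclose(field.vy[sel], (100 * gy / g2)[sel], rtol=1e-7)

    def test_noiseless_elliptical_on_axis_within_two_percent(self):
        model = WaveModel(pacing_site=(50, 50), v_long=0.51, v_trans=0.29,
                          long_axis_angle=20.0, pcl=150.0)
        T = compute_activation_field(model, (101, 101), pixel_size=0.035)
        rr, cc = np.indices(T.shape)
        mask = np.hypot(rr - 50, cc - 50) > 10  # away from the source
        field = fit_cv_bayly(T, pixel_size=0.035, mask=mask)
        # narrow cones: strictly on-axis speeds
        cv_l, cv_t = extract_axis_cv(field, 20.0, tolerance_deg=5.0,
                                     robust=False)
        assert cv_l == pytest.approx(51.0, rel=0.02)
        assert cv_t == pytest.approx(29.0, rel=0.02)

    def test_perturbed_activation_median_speed_error(self):
        rng = np.random.default_rng(5)
        v = 0.5  # mm/ms plane wave, 1 mm pixels
        x = np.arange(60) * 1.0
        T = np.broadcast_to(x / v, (60, 60)) + rng.normal(0, 0.5, (60, 60))
        field = fit_cv_bayly(T, pixel_size=1.0, residual_ms_max=np.inf)
        err = np.abs(field.speed[field.valid] - 50.0) / 50.0
        assert np.median(err) < 0.05

    def test_underdetermined_window_undefined(self):
        T = np.full((9, 9), np.nan)
        T[4, 4] = 1.0  # a lone pixel cannot support a 6-term fit
        field = fit_cv_bayly(T, pixel_size=0.1)
        assert not field.valid.any()


class TestExtractAxisCV:
    def _uniform_field(self, speed, angle_deg, n=50):
        ang = math.radians(angle_deg)
        vx = np.full((8, 8), speed * math.cos(ang))
        vy = np.full((8, 8), speed * math.sin(ang))
        return omkit.VelocityField(
            vx=vx, vy=vy, residual_ms=np.zeros((8, 8)),
            valid=np.ones((8, 8), bool), window=7, order=2, pixel_size=0.035)

    def test_uniform_field_recovers_speed(self):
        field = self._uniform_field(42.0, 30.0)
        cv_l, cv_t = extract_axis_cv(field, axis_angle_deg=30.0)
        assert cv_l == pytest.approx(42.0)
        assert np.isnan(cv_t)  # perpendicular cone is empty

    def test_opposite_direction_counts_toward_axis(self):
        field = self._uniform_field(42.0, 210.0)  # anti-parallel to the axis
        cv_l, _ = extract_axis_cv(field, axis_angle_deg=30.0)
        assert cv_l == pytest.approx(42.0)

    def test_empty_field_rejected(self):
        field = self._uniform_field(1.0, 0.0)
        field.valid[:] = False
        with pytest.raises(ValueError, match="no defined vectors"):
            extract_axis_cv(field, 0.0)

    def test_no_vectors_in_cone_warns_nan(self):
        field = self._uniform_field(10.0, 45.0)
        with pytest.warns(UserWarning, match="no vectors"):
            cv_l, cv_t = extract_axis_cv(field, axis_angle_deg=0.0,
                                         tolerance_deg=15.0)
        assert np.isnan(cv_l) and np.isnan(cv_t)


class TestRestitution:
    def test_single_pcl(self):
        curve = build_restitution([{"pcl": 150.0, "apd80_mean": 40.0}])
        assert len(curve.table) == 1

    def test_sorted_and_duplicates_rejected(self):
        curve = build_restitution([
            {"pcl": 80.0, "apd80_mean": 21.0},
            {"pcl": 150.0, "apd80_mean": 40.0},
        ])
        assert list(curve.pcls) == [150.0, 80.0]
        assert curve.table["apd80_mean"].iloc[0] - curve.table["apd80_mean"].iloc[1] == (
            pytest.approx(19.0))
        with pytest.raises(ValueError, match="duplicate"):
            build_restitution([
                {"pcl": 150.0, "apd80_mean": 40.0},
                {"pcl": 150.0, "apd80_mean": 41.0},
            ])
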