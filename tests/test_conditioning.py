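"""Conditioning chain: spatial filter, segmentation, ensemble averaging,
normalization, SNR definition, masking."""
from __future__ import annotations

import numpy as np
import pytest

import omkit
from omkit import (
    BeatWindows,
    SegmentationError,
    build_mask,
    compute_snr,
    ensemble_average,
    normalize_invert,
    segment_beats,
    spatial_gaussian_filter,
)
from omkit.conditioning import SNRComputationError
from omkit.synth import vignette_map


class TestSpatialGaussianFilter:
    def test_constant_frame_unchanged(self):
        frame = np.full((12, 12), 7.5)
        out = spatial_gaussian_filter(frame, window=5, sigma=1.0)
        np.testing.assert_allclose(out, 7.5, rtol=1e-6)

    def test_impulse_center_weight(self):
        # normalized separable weights for window 5, sigma 1:
        # (0.4026, 0.2442, 0.0545); center of the 2-D response = 0.4026^2
        frame = np.zeros((11, 11))
        frame[5, 5] = 1.0
        out = spatial_gaussian_filter(frame, window=5, sigma=1.0)
        assert out[5, 5] == pytest.approx(0.16210, abs=2e-4)
        assert out[5, 4] == pytest.approx(0.40262 * 0.24420, abs=2e-4)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_noise_sd_reduction_factor(self, rng):
        # 1 / sum(w^2) per axis, squared for 2-D -> SD shrinks ~3.48x
        frames = rng.standard_normal((10, 120, 120))
        out = spatial_gaussian_filter(frames, window=5, sigma=1.0)
        ratio = frames[:, 10:-10, 10:-10].std() / out[:, 10:-10, 10:-10].std()
        assert ratio == pytest.approx(3.481, rel=0.05)

    def test_linear_and_shift_equivariant(self, rng):
        a = rng.standard_normal((16, 16))
        b = rng.standard_normal((16, 16))
        f = lambda x: spatial_gaussian_filter(x, window=3, sigma=0.5)
        np.testing.assert_allclose(f(2.0 * a + 3.0 * b),
                                   2.0 * f(a) + 3.0 * f(b), atol=1e-5)
        shifted = np.roll(a, 2, axis=1)
        np.testing.assert_allclose(f(shifted)[:, 4:-4],
                                   np.roll(f(a), 2, axis=1)[:, 4:-4], atol=1e-5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            spatial_gaussian_filter(np.zeros((8, 8)), window=4)


class TestSegmentBeats:
    def _paced_trace(self, pcl=150.0, frame_rate=977.0, duration=2000.0):
        from omkit.synth import APTemplate, ap_train_value
        t = np.arange(int(round(duration * frame_rate / 1000))) * (1000 / frame_rate)
        v = ap_train_value(t - 10.0, APTemplate(), pcl)
        return 600.0 * (1.0 - 0.05 * v)

    def test_thirteen_beats_in_two_seconds_at_pcl150(self):
        windows = segment_beats(self._paced_trace(), pcl=150.0, frame_rate=977.0)
        assert windows.n_beats == 13

    def test_onsets_match_known_stimuli(self, small_mouse):
        sc, recording, truth = small_mouse
        filtered = spatial_gaussian_filter(recording.frames, 5, 1.0)
        windows = segment_beats(filtered, sc.wave.pcl, 977.0)
        onsets_ms = (windows.starts + windows.pre_frames) * (1000.0 / 977.0)
        # global upstroke trails each stimulus by a fixed propagation delay;
        # strides between detected onsets must match the pacing period
        strides = np.diff(onsets_ms)
        assert np.all(np.abs(strides - sc.wave.pcl) <= 1.5 * 1000.0 / 977.0)
        phase = onsets_ms[0] - truth.stimulus_times[0]
        assert 0.0 <= phase <= 25.0

    def test_recording_shorter_than_pcl_fails(self):
        with pytest.raises(SegmentationError, match="shorter"):
            segment_beats(self._paced_trace(duration=100.0), 150.0, 977.0)

    def test_flat_signal_fails(self):
        with pytest.raises(SegmentationError, match="flat"):
            segment_beats(np.full(400, 5.0), 150.0, 977.0)


class TestEnsembleAverage:
    def test_identical_beats_idempotent(self, rng):
        beat = rng.normal(size=(40, 6, 6))
        stack = np.stack([beat] * 5)
        avg = ensemble_average(stack, 977.0, 150.0)
        np.testing.assert_allclose(avg.traces, beat)
        assert avg.n_beats_averaged == 5

    def test_sqrt_n_noise_reduction(self, rng):
        sigma = 2.0
        stack = rng.normal(0.0, sigma, size=(13, 50, 40, 40))
        avg = ensemble_average(stack, 977.0, 150.0)
        assert avg.traces.std() == pytest.approx(sigma / np.sqrt(13), rel=0.15)

    def test_single_beat(self):
        beat = np.ones((10, 2, 2))
        avg = ensemble_average(beat[None], 977.0, 150.0)
        assert avg.n_beats_averaged == 1
        np.testing.assert_array_equal(avg.traces, beat)

    def test_ragged_beats_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            ensemble_average([np.zeros((10, 2)), np.zeros((11, 2))], 977.0, 150.0)

    def test_noiseless_conditioning_idempotent(self, noiseless_cond):
        # averaging identical noise-free beats returns the single-beat shape
        beat = noiseless_cond.beat.traces
        again = ensemble_average(beat[None], 977.0, 150.0)
        np.testing.assert_allclose(again.traces, beat)


class TestNormalizeInvert:
    def test_inverted_trace_spans_unit_interval(self):
        trace = np.array([200.0, 200.0, 100.0, 150.0, 200.0])[:, None]
        out, dead = normalize_invert(trace, resting_level=200.0)
        assert not dead[0]
        assert out.max() == pytest.approx(1.0)
        assert out[0, 0] == pytest.approx(0.0)
        assert np.argmax(out[:, 0]) == 2  # deepest dip becomes the peak

    def test_constant_trace_flagged_dead(self):
        out, dead = normalize_invert(np.full((8, 3), 5.0), resting_level=5.0)
        assert dead.all()
        np.testing.assert_array_equal(out, 0.0)

    def test_amplitude_independent_of_baseline_and_fraction(self):
        from omkit.synth import APTemplate, make_ap_trace
        v = make_ap_trace(APTemplate(), 150.0, 977.0, 1)
        for baseline, alpha in [(300.0, 0.02), (900.0, 0.12)]:
            trace = baseline * (1.0 - alpha * v)
            out, dead = normalize_invert(trace[:, None], resting_level=baseline)
            assert out.max() == pytest.approx(1.0)
            # rescaling by the sampled peak is the only transformation left
            np.testing.assert_allclose(out[:, 0], v / v.max(), atol=1e-9)


class TestComputeSNR:
    def _windows(self, L=30, frac=0.2):
        return BeatWindows(starts=np.array([0]), frames_per_beat=L,
                           pre_frames=0, frame_rate=1000.0, pcl=float(L),
                           diastolic_fraction=frac)

    def test_definition_ratio_of_rms(self):
        # deviation RMS 2.0 over the beat, diastolic RMS 1.0 -> SNR 2.0
        trace = np.empty(30)
        trace[:24] = np.sqrt((30 * 4.0 - 6.0) / 24.0)
        trace[24:] = [1, -1, 1, -1, 1, -1]
        snr = compute_snr(trace, self._windows(), resting_level=0.0,
                          correct_noise_bias=False)
        assert snr == pytest.approx(2.0)

    def test_noise_corrected_amplitude(self):
        trace = np.empty(30)
        trace[:24] = np.sqrt((30 * 4.0 - 6.0) / 24.0)
        trace[24:] = [1, -1, 1, -1, 1, -1]
        snr = compute_snr(trace, self._windows(), resting_level=0.0)
        assert snr == pytest.approx(np.sqrt(3.0))  # sqrt(4 - 1) / 1

    def test_noiseless_trace_infinite(self):
        trace = np.zeros(30)
        trace[5:10] = 1.0
        snr = compute_snr(trace, self._windows(), resting_level=0.0)
        assert np.isinf(snr)

    def test_window_outside_recording_rejected(self):
        with pytest.raises(SNRComputationError):
            compute_snr(np.zeros(20), self._windows(L=30), resting_level=0.0)

    def test_conditioned_snr_not_below_raw(self, small_cond):
        # stationary noise: binning + averaging can only help, in expectation
        m = small_cond.mask.keep
        assert m.sum() >= 1000
        assert (small_cond.snr_conditioned.masked_mean(m)
                > small_cond.snr_raw.masked_mean(m))


class TestBuildMask:
    def test_all_pixels_kept(self):
        mask = build_mask(np.full((4, 4), 10.0), np.full((4, 4), 500.0),
                          snr_cutoff=2.0, intensity_cutoff=100.0)
        assert mask.keep.all()
        assert mask.n_kept == 16

    def test_unreachable_cutoff_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            mask = build_mask(np.full((4, 4), 10.0), np.full((4, 4), 500.0),
                              snr_cutoff=2.0, intensity_cutoff=1e6)
        assert not mask.keep.any()

    def test_saturated_pixels_excluded(self):
        intensity = np.full((3, 3), 500.0)
        intensity[1, 1] = 1020.0  # above the 1% guard band of a 10-bit range
        mask = build_mask(np.full((3, 3), 10.0), intensity, 2.0, 100.0,
                          bits_per_sample=10)
        assert not mask.keep[1, 1]
        assert mask.keep.sum() == 8

    def test_vignette_disc_geometry(self):
        # cosine falloff 0.3 with cutoff at 0.8 x baseline keeps the
        # analytic disc r <= (2R/pi) * acos(1/3), within a 1-px band
        shape = (200, 200)
        baseline = 600.0 * vignette_map(shape, 0.3)
        mask = build_mask(np.full(shape, 10.0), baseline,
                          snr_cutoff=0.0, intensity_cutoff=480.0)
        rr, cc = np.indices(shape)
        dist = np.hypot(rr - 99.5, cc - 99.5)
        r_disc = (2 * 100.0 / np.pi) * np.arccos(1.0 / 3.0)
        assert mask.keep[dist <= r_disc - 1.0].all()
        assert not mask.keep[dist >= r_disc + 1.0].any()
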