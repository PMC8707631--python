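import numpy as np
import pytest

import emgforce as ef
from emgforce.preprocess import (bandpass_response, filter_chain, moving_average,
                                 notch_response)

FS = 1000.0


def steady_state_amplitude(y, fs, skip_s=1.0):
    """Peak amplitude of the trailing (post-transient) portion of a filtered sine."""
    return np.abs(y[int(skip_s * fs):]).max()


class TestRemoveDC:
    def test_constant_becomes_zero(self):
        np.testing.assert_array_equal(ef.remove_dc(np.array([2.0, 2, 2, 2])), 0.0)

    def test_offset_sine_recovered(self):
        t = np.arange(0, 2, 1 / FS)
        x = np.sin(2 * np.pi * 5 * t)
        # analytic oracle: subtracting the known 0.7 offset recovers the sine
        np.testing.assert_allclose(ef.remove_dc(x + 0.7), x - x.mean(), atol=1e-12)
        assert abs(ef.remove_dc(x + 0.7).mean()) < 1e-12

    def test_zero_mean_unchanged(self):
        x = np.array([-1.0, 1.0, -2.0, 2.0])
        np.testing.assert_allclose(ef.remove_dc(x), x, atol=1e-15)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            ef.remove_dc(np.array([1.0]))


class TestNotch:
    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(ef.notch_50hz(np.zeros(500), FS), 0.0)

    def test_50hz_attenuated(self):
        # oracle: designed filter's magnitude response at 50 Hz
        assert notch_response(FS, 50.0)[0] < 0.1
        t = np.arange(0, 3, 1 / FS)
        y = ef.notch_50hz(np.sin(2 * np.pi * 50 * t), FS)
        assert steady_state_amplitude(y, FS, 2.0) <= 0.1

    def test_100hz_passed(self):
        assert notch_response(FS, 100.0)[0] >= 0.9
        t = np.arange(0, 3, 1 / FS)
        y = ef.notch_50hz(np.sin(2 * np.pi * 100 * t), FS)
        assert steady_state_amplitude(y, FS, 2.0) >= 0.9

    def test_low_fs_errors(self):
        with pytest.raises(ValueError):
            ef.notch_50hz(np.zeros(100), 90.0)


class TestBandpass:
    def test_constant_decays_to_zero(self):
        y = ef.butterworth_bandpass(np.ones(3000), FS)
        assert np.abs(y[-500:]).max() < 1e-3

    def test_100hz_near_unity(self):
        # magnitude-response oracle at 100 Hz
        assert 0.95 <= bandpass_response(FS, 100.0)[0] <= 1.05
        t = np.arange(0, 4, 1 / FS)
        y = ef.butterworth_bandpass(np.sin(2 * np.pi * 100 * t), FS)
        assert 0.95 <= steady_state_amplitude(y, FS, 2.0) <= 1.05

    def test_2hz_rejected(self):
        assert bandpass_response(FS, 2.0)[0] <= 0.1
        t = np.arange(0, 6, 1 / FS)
        y = ef.butterworth_bandpass(np.sin(2 * np.pi * 2 * t), FS)
        assert steady_state_amplitude(y, FS, 4.0) <= 0.12

    def test_high_edge_clamped_below_nyquist(self):
        spec = ef.FilterSpec()  # nominal 500 Hz high edge at fs = 1000
        assert spec.effective_high(FS) == pytest.approx(495.0)
        # must not raise despite nominal edge at Nyquist
        ef.butterworth_bandpass(np.random.default_rng(0).standard_normal(1000), FS, spec)

    def test_invalid_edges_error(self):
        with pytest.raises(ValueError):
            ef.FilterSpec(bp_low=0.0)
        with pytest.raises(ValueError):
            ef.butterworth_bandpass(np.zeros(100), 15.0, ef.FilterSpec(bp_low=10, bp_high=500))

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError):
            ef.FilterSpec(bp_order=3)


class TestRectify:
    def test_mixed_signs(self):
        np.testing.assert_array_equal(
            ef.full_wave_rectify(np.array([-1.0, 2.0, -3.0])), [1.0, 2.0, 3.0])

    def test_nonnegative_identity(self):
        x = np.array([0.0, 1.5, 2.0])
        np.testing.assert_array_equal(ef.full_wave_rectify(x), x)

    def test_half_values(self):
        np.testing.assert_array_equal(
            ef.full_wave_rectify(np.array([-0.5, 0.0, 0.5])), [0.5, 0.0, 0.5])


class TestMVC:
    def test_rectified_constant(self):
        rec = ef.EMGRecording(fs=FS, channels={"biceps": np.full(1000, 0.5)},
                              force=np.zeros(1000))
        assert ef.compute_mvc(rec, "biceps", prefiltered=True) == pytest.approx(0.5)

    def test_synthetic_trial_matches_bruteforce_window_scan(self, dataset5):
        rec = dataset5[0]
        spec = ef.FilterSpec()
        mvc = ef.compute_mvc(rec, "biceps", spec)
        # brute-force oracle: scan every 0.2 s window of the rectified
        # filtered signal and take the best window mean
        x = ef.full_wave_rectify(filter_chain(rec.channels["biceps"], rec.fs, spec))
        k = int(0.2 * rec.fs)
        best = max(x[i:i + k].mean() for i in range(len(x) - k + 1))
        assert mvc == pytest.approx(best, rel=0.15)
        assert mvc > 0

    def test_zero_channel_errors(self):
        rec = ef.EMGRecording(fs=FS, channels={"biceps": np.zeros(1000)},
                              force=np.zeros(1000))
        with pytest.raises(ValueError, match="MVC"):
            ef.compute_mvc(rec, "biceps")

    def test_missing_channel_errors(self, dataset5):
        with pytest.raises(KeyError):
            ef.compute_mvc(dataset5[0], "deltoid")


class TestMVCNormalize:
    def test_value_at_mvc_is_one(self):
        assert ef.mvc_normalize(np.array([0.6]), 0.6)[0] == pytest.approx(1.0)

    def test_zero_maps_to_zero(self):
        assert ef.mvc_normalize(np.array([0.0]), 0.6)[0] == 0.0

    def test_half(self):
        assert ef.mvc_normalize(np.array([0.3]), 0.6)[0] == pytest.approx(0.5)

    def test_clamps_above_one(self):
        assert ef.mvc_normalize(np.array([1.2]), 0.6)[0] == 1.0

    def test_nonpositive_mvc_errors(self):
        with pytest.raises(ValueError):
            ef.mvc_normalize(np.array([0.1]), 0.0)


class TestChain:
    def test_mains_line_attenuated_at_least_20db(self):
        # spectrum oracle: 50 Hz line power before vs after the chain
        cfg = ef.SynthConfig(duration_s=4.0, mains_amp=0.3, seed=9)
        rec = ef.make_dataset(1, cfg)[0]
        raw = rec.channels["biceps"]
        filt = filter_chain(raw, rec.fs)
        n = len(raw)
        freqs = np.fft.rfftfreq(n, 1 / rec.fs)
        i50 = np.argmin(np.abs(freqs - 50.0))
        def line_power(x):
            return np.abs(np.fft.rfft(x - x.mean()))[i50 - 1:i50 + 2].max()
        atten_db = 20 * np.log10(line_power(raw) / line_power(filt))
        assert atten_db >= 20.0

    def test_normalized_in_unit_interval(self, dataset5):
        proc = ef.preprocess_chain(dataset5[0])
        for ch, x in proc.normalized.items():
            assert x.min() >= 0.0 and x.max() <= 1.0
            assert np.all(proc.rectified[ch] >= 0)

    def test_linearity_of_filtered_output(self, dataset5):
        rec = dataset5[1]
        mvc = {ch: 1.0 for ch in rec.channels}
        p1 = ef.preprocess_chain(rec, mvc_map=mvc)
        scaled = ef.EMGRecording(fs=rec.fs,
                                 channels={ch: 3.0 * v for ch, v in rec.channels.items()},
                                 force=rec.force)
        p3 = ef.preprocess_chain(scaled, mvc_map=mvc)
        np.testing.assert_allclose(p3.filtered["biceps"], 3.0 * p1.filtered["biceps"],
                                   rtol=1e-9, atol=1e-12)

    def test_sample_count_preserved(self, dataset5):
        rec = dataset5[0]
        proc = ef.preprocess_chain(rec)
        assert all(len(v) == rec.n_samples for v in proc.filtered.values())

    def test_external_mvc_map_used(self, dataset5):
        rec = dataset5[0]
        proc = ef.preprocess_chain(rec, mvc_map={"biceps": 0.5, "triceps": 0.5})
        assert proc.mvc == {"biceps": 0.5, "triceps": 0.5}

    def test_missing_mvc_entry_errors(self, dataset5):
        with pytest.raises(KeyError):
            ef.preprocess_chain(dataset5[0], mvc_map={"biceps": 0.5})


class TestMovingAverage:
    def test_constant_after_warmup(self):
        y = moving_average(np.ones(500), FS, 0.2)
        np.testing.assert_allclose(y[200:], 1.0)

    def test_causal_startup_ramp(self):
        # zero-padded causal boxcar ramps up over the first window
        y = moving_average(np.ones(500), FS, 0.2)
        assert len(y) == 500
        assert y[0] == pytest.approx(1 / 200)
        assert np.all(np.diff(y[:200]) > 0)
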