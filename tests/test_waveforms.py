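import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynphantom.waveforms import (
    BeatMorphology,
    SignalTrace,
    add_noise,
    max_normalize,
    read_trace_csv,
    resample,
    synth_ppg,
    write_trace_csv,
)


def local_minima(v):
    """Independent brute-force scan for strict local minima."""
    return [
        i
        for i in range(1, len(v) - 1)
        if v[i] < v[i - 1] and v[i] <= v[i + 1]
    ]


class TestSignalTrace:
    def test_duration_from_length_and_rate(self):
        t = SignalTrace(np.ones(500), 50.0)
        assert t.duration_s == 10.0
        assert t.times[0] == 0.0
        assert t.times[-1] == pytest.approx(9.98)

    @pytest.mark.parametrize(
        "values,rate",
        [([], 50.0), ([1.0], 0.0), ([1.0], -5.0), ([np.nan], 50.0)],
    )
    def test_invalid_construction_rejected(self, values, rate):
        with pytest.raises(ValueError):
            SignalTrace(np.asarray(values, dtype=float), rate)


class TestSynthPpg:
    def test_paper_record_length(self):
        trace = synth_ppg(80, 20.0, 1000.0, seed=1)
        assert trace.n_samples == 20000
        assert trace.sampling_rate == 1000.0

    def test_exact_periodicity_without_jitter(self):
        trace = synth_ppg(60, 4.0, 100.0, hr_jitter_frac=0.0, seed=1)
        lag = 100  # 60 bpm at 100 Hz
        v = trace.values
        assert np.max(np.abs(v[:-lag] - v[lag:])) < 1e-9

    def test_two_beats_autocorrelation_peak(self):
        trace = synth_ppg(60, 2.0, 100.0, seed=1)
        assert trace.n_samples == 200
        x = trace.values - trace.values.mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1 :]
        lag = int(np.argmax(ac[50:150])) + 50
        assert abs(lag - 100) <= 2  # finite two-period record biases slightly

    def test_mean_intertrough_interval_120bpm(self):
        # independent oracle: brute-force local-minimum scan
        trace = synth_ppg(120, 20.0, 1000.0, seed=1)
        minima = local_minima(trace.values)
        # keep only beat-scale minima: drop any closer than 0.3 s
        kept = [minima[0]]
        for m in minima[1:]:
            if m - kept[-1] > 300:
                kept.append(m)
        intervals = np.diff(kept) / 1000.0
        assert intervals.mean() == pytest.approx(0.500, abs=0.002)

    def test_beat_has_systolic_diastolic_and_notch(self):
        trace = synth_ppg(60, 1.0, 500.0, seed=1)
        v = trace.values
        peaks = [i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] >= v[i + 1]]
        assert len(peaks) == 2  # systolic + diastolic
        assert v[peaks[0]] > v[peaks[1]]
        notch = [m for m in local_minima(v) if peaks[0] < m < peaks[1]]
        assert len(notch) == 1

    def test_deterministic_given_seed(self):
        a = synth_ppg(90, 5.0, 250.0, hr_jitter_frac=0.05, seed=7)
        b = synth_ppg(90, 5.0, 250.0, hr_jitter_frac=0.05, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(heart_rate_bpm=20),
            dict(heart_rate_bpm=300),
            dict(duration_s=0.0),
            dict(duration_s=-1.0),
            dict(sampling_rate_hz=3.0),  # below 4 samples/beat at 80 bpm
        ],
    )
    def test_preconditions(self, kwargs):
        args = dict(heart_rate_bpm=80, duration_s=5.0, sampling_rate_hz=100.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            synth_ppg(**args)

    def test_morphology_validation(self):
        with pytest.raises(ValueError):
            BeatMorphology(diastolic_amplitude=2.0)  # above systolic
        with pytest.raises(ValueError):
            BeatMorphology(systolic_width=0.0)


class TestMaxNormalize:
    def test_simple_division(self):
        out = max_normalize(SignalTrace(np.array([2.0, 4.0, 8.0]), 1.0))
        np.testing.assert_allclose(out.values, [0.25, 0.5, 1.0])

    def test_constant_positive_trace(self):
        out = max_normalize(SignalTrace(np.full(10, 3.7), 1.0))
        np.testing.assert_array_equal(out.values, np.ones(10))

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError):
            max_normalize(SignalTrace(np.array([-1.0, -2.0, 0.0]), 1.0))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=1000), min_size=2, max_size=50
        ).filter(lambda v: max(v) > 0)
    )
    def test_idempotent_and_peaks_at_one(self, values):
        trace = SignalTrace(np.asarray(values), 10.0)
        once = max_normalize(trace)
        assert once.values.max() == pytest.approx(1.0, abs=1e-12)
        twice = max_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


class TestResample:
    def test_downsample_count(self):
        trace = SignalTrace(np.ones(20000), 1000.0)
        out = resample(trace, 50.0)
        assert out.n_samples == 1000
        assert abs(out.duration_s - trace.duration_s) <= 1.0 / 50.0

    def test_same_rate_is_identity(self):
        trace = SignalTrace(np.arange(100, dtype=float), 100.0)
        out = resample(trace, 100.0)
        np.testing.assert_array_equal(out.values, trace.values)

    def test_sine_agrees_with_analytic_interpolant(self):
        t = np.arange(5000) / 1000.0
        trace = SignalTrace(np.sin(2 * np.pi * 2.0 * t), 1000.0)
        out = resample(trace, 50.0)
        expected = np.sin(2 * np.pi * 2.0 * np.arange(out.n_samples) / 50.0)
        assert np.max(np.abs(out.values - expected)) < 1e-3

    def test_round_trip_band_limited(self):
        t = np.arange(2000) / 200.0
        trace = SignalTrace(1.5 + np.sin(2 * np.pi * 1.3 * t), 200.0)
        back = resample(resample(trace, 100.0), 200.0)
        # the final fine-grid sample lies beyond the last coarse sample and
        # cannot be recovered by interpolation; compare the interior
        err = np.abs(back.values[:-2] - trace.values[:-2])
        assert np.max(err) < 1e-3 * np.ptp(trace.values) + 1e-3


class TestAddNoise:
    def test_zero_magnitude_identity(self):
        trace = SignalTrace(np.arange(50, dtype=float) + 1, 10.0)
        out = add_noise(trace, "white", 0.0, seed=1)
        np.testing.assert_array_equal(out.values, trace.values)

    def test_white_noise_std(self):
        trace = SignalTrace(np.full(100_000, 5.0), 100.0)
        out = add_noise(trace, "white", 0.01, seed=2)
        assert np.std(out.values - trace.values) == pytest.approx(0.01, abs=2e-4)

    def test_drift_is_slow_sinusoid(self):
        trace = SignalTrace(np.zeros(10_000), 100.0)
        out = add_noise(trace, "drift", 0.5, seed=3)
        spectrum = np.abs(np.fft.rfft(out.values))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 100.0)
        assert freqs[np.argmax(spectrum[1:]) + 1] < 0.5
        assert np.max(np.abs(out.values)) <= 0.5 + 1e-9

    def test_spikes_sparse_and_positive(self):
        trace = SignalTrace(np.zeros(5000), 50.0)
        out = add_noise(trace, "spikes", 2.0, seed=4)
        delta = out.values - trace.values
        assert 0 < np.count_nonzero(delta) < 0.05 * trace.n_samples
        assert np.allclose(delta[delta != 0] % 2.0, 0)

    def test_deterministic_given_seed(self):
        trace = SignalTrace(np.zeros(1000), 50.0)
        for kind in ("white", "drift", "spikes"):
            a = add_noise(trace, kind, 0.1, seed=11)
            b = add_noise(trace, kind, 0.1, seed=11)
            np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="noise_kind"):
            add_noise(SignalTrace(np.ones(10), 1.0), "pink", 0.1)


class TestCsvRoundTrip:
    def test_write_read(self, tmp_path):
        trace = synth_ppg(75, 2.0, 100.0, seed=5)
        path = tmp_path / "ppg.csv"
        write_trace_csv(trace, path)
        back = read_trace_csv(path)
        assert back.sampling_rate == pytest.approx(100.0, rel=1e-9)
        np.testing.assert_allclose(back.values, trace.values, atol=1e-12)

    def test_nonuniform_grid_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,value\n0.0,1.0\n0.1,1.0\n0.3,1.0\n")
        with pytest.raises(ValueError, match="uniform"):
            read_trace_csv(path)
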