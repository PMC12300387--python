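"""Rate-of-change envelope, peak detection, epoch averaging, minima mapping."""

import numpy as np
import pytest

from fpiapw import (
    compute_envelope,
    detect_envelope_peaks,
    detect_epoch_minima,
    epoch_average,
)
from fpiapw.envelope_features import EnvelopeResult, EpochAverage


def env_from(time_s, smoothed, envelope=None):
    envelope = smoothed if envelope is None else envelope
    return EnvelopeResult(
        time_s=np.asarray(time_s, float),
        rate_of_change=np.zeros_like(smoothed, dtype=float),
        envelope=np.asarray(envelope, float),
        smoothed_envelope=np.asarray(smoothed, float),
    )


class TestComputeEnvelope:
    def test_linear_ramp_has_constant_rate(self):
        t = np.arange(0, 10, 1e-3)
        env = compute_envelope(t, 3.0 * t, trim_s=0.5, band=(0.5, 10))
        assert np.allclose(env.rate_of_change, 3.0, atol=1e-6)

    def test_tone_envelope_is_flat_at_derivative_amplitude(self):
        t = np.arange(0, 20, 1e-3)
        a, f = 0.5, 10.0
        env = compute_envelope(t, a * np.cos(2 * np.pi * f * t),
                               trim_s=1.0, band=(0.5, 10))
        expected = a * 2 * np.pi * f
        mid = env.envelope[env.envelope.size // 4:-env.envelope.size // 4]
        raw_mid = np.abs(
            np.max(np.abs(env.rate_of_change))
        )
        assert raw_mid == pytest.approx(expected, rel=0.01)
        # envelope is max-normalized, flat within 5% mid-span
        assert mid.min() > 0.95 * mid.max()
        assert env.envelope.max() == pytest.approx(1.0)

    def test_envelope_nonnegative_and_normalized(self, clean_roundtrip):
        env = clean_roundtrip[2].envelope
        assert np.all(env.envelope >= 0.0)
        assert env.envelope.max() == pytest.approx(1.0)

    def test_excessive_trim_rejected(self):
        t = np.arange(0, 2, 1e-3)
        with pytest.raises(ValueError, match="trim"):
            compute_envelope(t, np.sin(t), trim_s=1.5, band=(0.5, 10))

    def test_inverted_band_rejected(self):
        t = np.arange(0, 5, 1e-3)
        with pytest.raises(ValueError, match="band"):
            compute_envelope(t, np.sin(t), trim_s=0.1, band=(10, 0.5))


class TestDetectEnvelopePeaks:
    def bumps(self, centers, width=0.05, fs=1000.0, heights=None):
        t = np.arange(0, 4, 1 / fs)
        x = np.zeros_like(t)
        heights = heights or [1.0] * len(centers)
        for c, h in zip(centers, heights):
            x += h * np.exp(-0.5 * ((t - c) / width) ** 2)
        return env_from(t, x)

    def test_two_bumps_resolved(self):
        env = self.bumps([1.0, 2.0])
        peaks = detect_envelope_peaks(env, min_height=0.3, min_distance_s=0.5)
        # oracle: exhaustive local-maximum scan
        x = env.smoothed_envelope
        oracle = [
            env.time_s[i] for i in range(1, x.size - 1)
            if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] >= 0.3
        ]
        assert np.allclose(peaks, oracle, atol=1e-3)
        assert peaks.size == 2

    def test_distance_rule_keeps_taller_bump(self):
        env = self.bumps([1.0, 2.0], heights=[0.8, 1.0])
        peaks = detect_envelope_peaks(env, min_height=0.3, min_distance_s=1.5)
        assert peaks.size == 1
        assert peaks[0] == pytest.approx(2.0, abs=1e-3)

    def test_flat_envelope_yields_nothing(self):
        t = np.arange(0, 2, 1e-3)
        env = env_from(t, np.full_like(t, 0.5))
        assert detect_envelope_peaks(env, 0.3, 0.5).size == 0

    def test_min_distance_respected(self, clean_roundtrip):
        result = clean_roundtrip[2]
        assert np.all(np.diff(result.peak_times) >= 0.5)


class TestEpochAverage:
    def test_identical_epochs_have_zero_ci_width(self):
        t = np.arange(0, 10, 1e-2)
        x = np.sin(2 * np.pi * t)  # period 1 s, epochs at integer times
        avg = epoch_average(t, x, [2.0, 3.0, 4.0], window=(-0.5, 0.5))
        assert avg.epoch_count == 3
        assert np.allclose(avg.ci_upper - avg.ci_lower, 0.0, atol=1e-12)
        rel = np.sin(2 * np.pi * avg.epoch_time_s)
        assert np.allclose(avg.mean_signal, rel, atol=1e-9)

    def test_antisymmetric_epochs_average_to_zero(self):
        t = np.arange(0, 4, 1e-2)
        x = np.concatenate([np.ones(200), -np.ones(200)])
        avg = epoch_average(t, x, [1.0, 3.0], window=(-0.5, 0.5))
        assert np.allclose(avg.mean_signal, 0.0)

    def test_ci_halfwidth_matches_normal_theory(self):
        # 100 epochs of iid N(0,1): pointwise 95% CI halfwidth ~ 1.96/sqrt(100)
        rng = np.random.default_rng(11)
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        x = rng.normal(size=t.size)
        peaks = np.arange(5.0, 105.0, 1.0)
        avg = epoch_average(t, x, peaks, window=(-0.2, 0.2))
        half = (avg.ci_upper - avg.ci_lower) / 2
        assert np.mean(half) == pytest.approx(0.196, rel=0.2)

    def test_out_of_bounds_epochs_dropped_and_counted(self):
        t = np.arange(0, 5, 1e-2)
        avg = epoch_average(t, np.sin(t), [0.1, 2.5, 4.9], window=(-0.5, 0.5))
        assert avg.epoch_count == 1
        assert avg.dropped_count == 2

    def test_no_usable_epoch_raises(self):
        t = np.arange(0, 1, 1e-2)
        with pytest.raises(ValueError, match="no epoch"):
            epoch_average(t, np.sin(t), [0.0], window=(-2.0, 2.0))


class TestDetectEpochMinima:
    def make_avg(self, rel_t, mean):
        mean = np.asarray(mean, float)
        return EpochAverage(
            epoch_time_s=np.asarray(rel_t, float), mean_signal=mean,
            ci_lower=mean, ci_upper=mean, epoch_count=1,
        )

    def test_single_trough_of_inverted_cosine(self):
        rel = np.linspace(-0.5, 0.5, 501)
        avg = self.make_avg(rel, -np.cos(2 * np.pi * rel))
        cat = detect_epoch_minima(avg, [3.0], min_distance_s=0.05)
        assert len(cat) == 1
        assert cat.absolute_time_s[0] == pytest.approx(3.0, abs=2e-3)

    def test_monotonic_mean_has_no_minima(self):
        rel = np.linspace(-0.5, 0.5, 201)
        cat = detect_epoch_minima(self.make_avg(rel, rel * 2.0), [1.0])
        assert len(cat) == 0

    def test_minima_mapped_to_every_peak(self):
        # troughs at rel {0.1, 0.4} and peaks {2, 3} -> {2.1, 2.4, 3.1, 3.4}
        rel = np.linspace(0.0, 0.5, 501)
        mean = np.cos(2 * np.pi * (rel - 0.1) / 0.6) + np.cos(
            2 * np.pi * (rel - 0.4) / 0.6
        )
        mean = -np.exp(-0.5 * ((rel - 0.1) / 0.03) ** 2) - np.exp(
            -0.5 * ((rel - 0.4) / 0.03) ** 2
        )
        cat = detect_epoch_minima(self.make_avg(rel, mean), [2.0, 3.0],
                                  min_distance_s=0.05)
        assert np.allclose(cat.absolute_time_s, [2.1, 2.4, 3.1, 3.4], atol=2e-3)

    def test_drop_first_and_last(self):
        rel = np.linspace(0.0, 0.5, 501)
        mean = -np.exp(-0.5 * ((rel - 0.1) / 0.03) ** 2) - np.exp(
            -0.5 * ((rel - 0.4) / 0.03) ** 2
        )
        cat = detect_epoch_minima(self.make_avg(rel, mean), [2.0, 3.0],
                                  min_distance_s=0.05, drop_first=1, drop_last=1)
        assert np.allclose(cat.absolute_time_s, [2.4, 3.1], atol=2e-3)

    def test_catalog_times_strictly_increasing(self, clean_roundtrip):
        cat = clean_roundtrip[2].minima
        assert np.all(np.diff(cat.absolute_time_s) > 0)

    def test_csv_round_trip(self, tmp_path, clean_roundtrip):
        from fpiapw.envelope_features import MinimaCatalog
        import pandas as pd

        cat = clean_roundtrip[2].minima
        path = tmp_path / "minima.csv"
        cat.write_csv(path)
        back = MinimaCatalog.from_frame(pd.read_csv(path))
        assert np.allclose(back.absolute_time_s, cat.absolute_time_s)
        assert np.allclose(back.amplitude, cat.amplitude)


class TestEnvelopePeaksTrackUpstrokes:
    @pytest.mark.parametrize("noise_pct", [0.0, 5.0])
    def test_peaks_within_100ms_of_systole_onsets(self, template, optics,
                                                  noise_pct):
        from fpiapw import run_auto_pipeline, synthesize_recording

        noise_sd = noise_pct / 100.0 * optics.fringe_amplitude
        rec = synthesize_recording(template, optics, noise_sd=noise_sd, seed=9)
        result = run_auto_pipeline(rec.trace, optics)
        onsets = rec.events("systole_start")
        for pt in result.peak_times:
            assert np.min(np.abs(onsets - pt)) < 0.1
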