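"""Classical surrogate-respiration methods and temporal alignment."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from ppgresp import (SignalChannel, SimulationConfig, align_to_reference,
                     detect_beats, extract_feature_based,
                     extract_filter_based, extract_surrogate,
                     simulate_recording)
from ppgresp.preprocessing import FEATURE_RATE_HZ, resample_channel
from ppgresp.surrogates import CLASSICAL_METHODS, SurrogateWaveform, _beat_series


def _dominant_freq(x, rate):
    x = x - np.mean(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / rate)
    return freqs[np.argmax(np.abs(np.fft.rfft(x)))]


def _sim25(**kwargs):
    rec = simulate_recording(SimulationConfig(**kwargs))
    ppg25 = resample_channel(rec.ppg, FEATURE_RATE_HZ)
    rtv25 = resample_channel(rec.rtv, FEATURE_RATE_HZ)
    return ppg25, rtv25


class TestFilterBased:
    def test_cwt_envelope_modulates_at_breathing_frequency(self, am_ppg25):
        out = extract_filter_based(am_ppg25, "X_A2")
        assert _dominant_freq(out.samples, out.rate_hz) == pytest.approx(
            10.0 / 60.0, abs=0.01)

    def test_cwt_envelope_flat_without_modulation(self, am_ppg25):
        ppg_flat, _ = _sim25(duration_s=120, breathing_rate_bpm=10,
                             heart_rate_bpm=72, am_depth=0, bw_amplitude=0,
                             fm_depth=0, noise_sd=0, seed=5)
        modulated = extract_filter_based(am_ppg25, "X_A2")
        flat = extract_filter_based(ppg_flat, "X_A2")
        # compare away from the transform's edge cone (10 s each side)
        sl = slice(250, -250)
        assert np.std(flat.samples[sl]) < 0.1 * np.std(modulated.samples[sl])

    def test_cwt_ridge_frequency_tracks_fm(self):
        ppg25, rtv25 = _sim25(duration_s=120, breathing_rate_bpm=10,
                              heart_rate_bpm=66, am_depth=0, bw_amplitude=0,
                              fm_depth=0.1, noise_sd=0, seed=6)
        out = extract_filter_based(ppg25, "X_A3")
        aligned = align_to_reference(out, rtv25, 10.0)
        r = pearsonr(aligned.samples, rtv25.samples).statistic
        assert abs(r) > 0.6

    def test_unknown_method_rejected(self, am_ppg25):
        with pytest.raises(ValueError):
            extract_filter_based(am_ppg25, "X_B1")


class TestFeatureBased:
    def test_amplitude_difference_tracks_reference(self, am_ppg25, am_rtv25):
        beats = detect_beats(am_ppg25)
        out = extract_feature_based(am_ppg25, beats, "X_B2")
        aligned = align_to_reference(out, am_rtv25, 10.0)
        assert pearsonr(aligned.samples, am_rtv25.samples).statistic > 0.8

    def test_trough_interval_series_mean_matches_beat_interval(self):
        ppg25, _ = _sim25(duration_s=120, breathing_rate_bpm=10,
                          heart_rate_bpm=66, am_depth=0, bw_amplitude=0,
                          fm_depth=0.1, noise_sd=0, seed=6)
        beats = detect_beats(ppg25)
        _, values = _beat_series(ppg25, beats, "X_B3")
        assert np.mean(values) == pytest.approx(60.0 / 66.0, rel=0.02)

    def test_peak_minus_trough_reproduces_amplitude_difference(self, am_ppg25):
        beats = detect_beats(am_ppg25)
        _, b5 = _beat_series(am_ppg25, beats, "X_B5")
        _, b6 = _beat_series(am_ppg25, beats, "X_B6")
        _, b2 = _beat_series(am_ppg25, beats, "X_B2")
        assert np.max(np.abs((b5[1:] - b6) - b2)) < 1e-9

    def test_too_few_beats_rejected(self, am_ppg25):
        short = SignalChannel(am_ppg25.samples[:30], am_ppg25.rate_hz)
        with pytest.raises(ValueError):
            extract_feature_based(short, detect_beats(short), "X_B2")

    @pytest.mark.parametrize("method", CLASSICAL_METHODS)
    def test_outputs_finite_and_length_matched(self, am_ppg25, am_rtv25, method):
        out = extract_surrogate(am_ppg25, method)
        assert np.all(np.isfinite(out.samples))
        n = min(len(out), len(am_rtv25))
        aligned = align_to_reference(
            SurrogateWaveform(out.samples[:n], out.rate_hz, method),
            SignalChannel(am_rtv25.samples[:n], am_rtv25.rate_hz), 10.0)
        assert len(aligned) == n


class TestAlignment:
    def test_recovers_known_shift(self):
        rng = np.random.default_rng(7)
        rate = 25.0
        # band-limited noise: sharp autocorrelation, unambiguous lag
        from scipy.signal import butter, sosfiltfilt
        sos = butter(2, 2.0 / (rate / 2), output="sos")
        x = sosfiltfilt(sos, rng.normal(size=2000))
        ref = SignalChannel(x, rate)
        shifted = np.concatenate([np.zeros(50), x[:-50]])  # +2.0 s delay
        sur = SurrogateWaveform(shifted, rate, "X_A1")
        aligned = align_to_reference(sur, ref, 5.0)
        assert aligned.lag_applied_s == pytest.approx(-2.0, abs=1.0 / rate)

    def test_zero_max_lag_is_identity(self, am_rtv25):
        sur = SurrogateWaveform(am_rtv25.samples, am_rtv25.rate_hz, "X_A1")
        aligned = align_to_reference(sur, am_rtv25, 0.0)
        assert np.array_equal(aligned.samples, sur.samples)
        assert aligned.lag_applied_s == 0.0

    def test_max_lag_beyond_half_signal_rejected(self, am_rtv25):
        sur = SurrogateWaveform(am_rtv25.samples, am_rtv25.rate_hz, "X_A1")
        with pytest.raises(ValueError):
            align_to_reference(sur, am_rtv25, am_rtv25.duration_s)

    def test_independent_noise_gains_little_from_alignment(self):
        # max-lag search bias must stay small for unrelated signals
        rng = np.random.default_rng(8)
        rate = 25.0
        a = rng.normal(size=3000)
        b = rng.normal(size=3000)
        ref = SignalChannel(a, rate)
        aligned = align_to_reference(SurrogateWaveform(b, rate, "X_A1"), ref,
                                     5.0)
        r_aligned = abs(pearsonr(aligned.samples, a).statistic)
        # permutation yardstick: best |r| over the same number of shifts
        null = max(abs(pearsonr(np.roll(b, k), a).statistic)
                   for k in range(-125, 126, 5))
        assert r_aligned <= null + 0.05


class TestMonotoneDegradation:
    def test_correlation_degrades_with_noise(self):
        noise_levels = (0.0, 0.05, 0.1, 0.2)
        seeds = range(10)
        mean_r = {"X_A2": [], "X_B2": []}
        for noise in noise_levels:
            rs = {"X_A2": [], "X_B2": []}
            for seed in seeds:
                ppg25, rtv25 = _sim25(duration_s=90, breathing_rate_bpm=10,
                                      heart_rate_bpm=70, am_depth=0.3,
                                      bw_amplitude=0.1, fm_depth=0.05,
                                      noise_sd=noise, seed=100 + seed)
                for method in rs:
                    out = extract_surrogate(ppg25, method)
                    aligned = align_to_reference(out, rtv25, 10.0)
                    rs[method].append(
                        pearsonr(aligned.samples, rtv25.samples).statistic)
            for method in mean_r:
                mean_r[method].append(np.mean(rs[method]))
        for method, series in mean_r.items():
            diffs = np.diff(series)
            assert np.all(diffs <= 0.02), (method, series)
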