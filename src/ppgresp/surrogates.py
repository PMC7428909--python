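"""Classical surrogate-respiration extraction from a PPG.

Ten filter-based and feature-based algorithms, each producing a
respiration-like waveform from the pulse signal:

==========  ==========================================================
X_A1        Bandpass filter over plausible respiratory frequencies
X_A2        Maximum CWT amplitude within plausible cardiac
            frequencies (30-220 beats/min)
X_A3        Frequency attaining that CWT maximum
X_B1        Mean amplitude of troughs and proceeding peaks
X_B2        Peak-minus-trough amplitude difference
X_B3        Time interval between consecutive troughs
X_B4        Mean signal value between consecutive troughs
X_B5        Peak amplitude
X_B6        Trough amplitude
X_B10       Pulse width (50% fractional-amplitude wave boundaries)
==========  ==========================================================

Identifiers X_B7-X_B9 are deliberately absent; the numbering gap is the
field's, kept verbatim.  X_LSTM tags waveforms predicted by the
sequence model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .beats import BeatAnnotations, detect_beats
from .simulate import SignalChannel

__all__ = [
    "SurrogateWaveform",
    "FILTER_METHODS",
    "FEATURE_METHODS",
    "CLASSICAL_METHODS",
    "extract_filter_based",
    "extract_feature_based",
    "extract_surrogate",
    "align_to_reference",
]

FILTER_METHODS = ("X_A1", "X_A2", "X_A3")
FEATURE_METHODS = ("X_B1", "X_B2", "X_B3", "X_B4", "X_B5", "X_B6", "X_B10")
CLASSICAL_METHODS = FILTER_METHODS + FEATURE_METHODS
ALL_METHODS = CLASSICAL_METHODS + ("X_LSTM",)

#: Plausible respiratory band: 4-36 breaths/min.
RESP_BAND_HZ = (4.0 / 60.0, 36.0 / 60.0)
#: Plausible cardiac band: 30-220 beats/min.
CARDIAC_BAND_HZ = (0.5, 220.0 / 60.0)

_CWT_WAVELET = "cmor1.5-1.0"
_CWT_N_FREQS = 40


@dataclass(frozen=True)
class SurrogateWaveform:
    """A derived respiratory waveform tagged with its method identifier."""

    samples: np.ndarray
    rate_hz: float
    method_id: str
    lag_applied_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.method_id not in ALL_METHODS:
            raise ValueError(f"unknown method_id {self.method_id!r}")

    def __len__(self) -> int:
        return self.samples.size


def _cwt_cardiac(ppg25: SignalChannel) -> tuple[np.ndarray, np.ndarray]:
    """|CWT| over log-spaced pseudo-frequencies in the cardiac band."""
    freqs = np.geomspace(CARDIAC_BAND_HZ[0], CARDIAC_BAND_HZ[1], _CWT_N_FREQS)
    scales = pywt.frequency2scale(_CWT_WAVELET, freqs / ppg25.rate_hz)
    coef, actual = pywt.cwt(ppg25.samples - ppg25.samples.mean(), scales,
                            _CWT_WAVELET, sampling_period=1.0 / ppg25.rate_hz,
                            method="fft")
    return np.abs(coef), actual


def extract_filter_based(ppg25: SignalChannel, method_id: str) -> SurrogateWaveform:
    """X_A1 (respiratory bandpass) and X_A2/X_A3 (cardiac CWT envelope/ridge)."""
    if method_id == "X_A1":
        nyq = ppg25.rate_hz / 2.0
        sos = butter(2, [RESP_BAND_HZ[0] / nyq, RESP_BAND_HZ[1] / nyq],
                     btype="bandpass", output="sos")
        out = sosfiltfilt(sos, ppg25.samples)
        return SurrogateWaveform(out, ppg25.rate_hz, method_id)
    if method_id in ("X_A2", "X_A3"):
        mag, freqs = _cwt_cardiac(ppg25)
        if method_id == "X_A2":
            out = mag.max(axis=0)
        else:
            out = freqs[np.argmax(mag, axis=0)]
        return SurrogateWaveform(out, ppg25.rate_hz, method_id)
    raise ValueError(f"unknown filter-based method {method_id!r}")


def _beat_series(ppg25: SignalChannel, beats: BeatAnnotations,
                 method_id: str) -> tuple[np.ndarray, np.ndarray]:
    """(anchor times, per-beat values) for a feature-based method."""
    x = ppg25.samples
    fs = ppg25.rate_hz
    p, t = beats.peak_indices, beats.trough_indices
    if method_id == "X_B1":
        # Trough and the peak proceeding from it.
        times = p[1:] / fs
        values = 0.5 * (x[t] + x[p[1:]])
    elif method_id == "X_B2":
        times = p[1:] / fs
        values = x[p[1:]] - x[t]
    elif method_id == "X_B3":
        times = 0.5 * (t[1:] + t[:-1]) / fs
        values = np.diff(t) / fs
    elif method_id == "X_B4":
        times = 0.5 * (t[1:] + t[:-1]) / fs
        values = np.array([x[a:b + 1].mean() for a, b in zip(t[:-1], t[1:])])
    elif method_id == "X_B5":
        times = p / fs
        values = x[p]
    elif method_id == "X_B6":
        times = t / fs
        values = x[t]
    elif method_id == "X_B10":
        ok = np.isfinite(beats.pulse_widths_s)
        times = p[ok] / fs
        values = beats.pulse_widths_s[ok]
    else:
        raise ValueError(f"unknown feature-based method {method_id!r}")
    return np.asarray(times, float), np.asarray(values, float)


def extract_feature_based(ppg25: SignalChannel, beats: BeatAnnotations,
                          method_id: str) -> SurrogateWaveform:
    """Per-beat scalar series, interpolated to a uniform 25 Hz waveform.

    Cubic-spline interpolation over beat anchor times (linear for fewer
    than 4 beats); the grid is clamped to the anchor span so edge values
    are held rather than extrapolated.
    """
    if beats.empty or beats.n_beats < 3:
        raise ValueError("need at least 3 detected beats for feature-based methods")
    times, values = _beat_series(ppg25, beats, method_id)
    if times.size < 2:
        raise ValueError(f"too few beat anchors for {method_id}")
    grid = np.arange(len(ppg25)) / ppg25.rate_hz
    clamped = np.clip(grid, times[0], times[-1])
    if times.size >= 4:
        out = CubicSpline(times, values)(clamped)
    else:
        out = np.interp(clamped, times, values)
    return SurrogateWaveform(out, ppg25.rate_hz, method_id)


def extract_surrogate(ppg25: SignalChannel, method_id: str,
                      beats: BeatAnnotations | None = None) -> SurrogateWaveform:
    """Dispatch to the filter- or feature-based extractor for ``method_id``."""
    if method_id in FILTER_METHODS:
        return extract_filter_based(ppg25, method_id)
    if method_id in FEATURE_METHODS:
        if beats is None:
            beats = detect_beats(ppg25)
        return extract_feature_based(ppg25, beats, method_id)
    raise ValueError(f"unknown method_id {method_id!r}")


def align_to_reference(surrogate: SurrogateWaveform, reference: SignalChannel,
                       max_lag_s: float = 10.0) -> SurrogateWaveform:
    """Shift the surrogate to maximize cross-correlation with the reference.

    The search is bounded to |lag| <= ``max_lag_s``; vacated edge samples
    are zero-filled (on the mean-removed signal) and the applied lag is
    recorded in ``lag_applied_s``.
    """
    if abs(surrogate.rate_hz - reference.rate_hz) > 1e-9:
        raise ValueError("surrogate and reference must share a sampling rate")
    if max_lag_s < 0:
        raise ValueError("max_lag_s must be non-negative")
    n = len(reference)
    if len(surrogate) != n:
        raise ValueError("surrogate and reference must have equal length")
    max_lag = int(round(max_lag_s * reference.rate_hz))
    if max_lag > n // 2:
        raise ValueError("max_lag_s exceeds half the signal duration")
    if max_lag == 0:
        return replace(surrogate, lag_applied_s=0.0)

    sur = surrogate.samples - surrogate.samples.mean()
    ref = np.asarray(reference.samples, float) - np.mean(reference.samples)
    full = np.correlate(ref, sur, mode="full")  # index k <-> lag k-(n-1)
    lags = np.arange(-(n - 1), n)
    window = (lags >= -max_lag) & (lags <= max_lag)
    # normalize by overlap length so long overlaps do not dominate
    overlap = n - np.abs(lags[window])
    best = lags[window][np.argmax(full[window] / overlap)]

    shifted = np.zeros(n)
    if best >= 0:
        shifted[best:] = sur[: n - best]
    else:
        shifted[:best] = sur[-best:]
    shifted += surrogate.samples.mean()
    return SurrogateWaveform(shifted, surrogate.rate_hz, surrogate.method_id,
                             lag_applied_s=best / surrogate.rate_hz)
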