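"""Breathing metrics from a tidal-volume-like waveform.

A derived (or reference) respiratory waveform is first screened for
validity (Pearson r against the reference, threshold 0.6), optionally
Savitzky-Golay smoothed, then segmented into breaths: peaks are
prominent local maxima bounded by the plausible respiratory band, and
each trough is the global minimum between consecutive peaks.  From the
peak/trough sequence the window-averaged interbreath interval (IBI),
inspiration time (trough to next peak), expiration period (peak to next
trough), breathing rate (60/IBI) and I:E ratio are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import pearsonr

from .preprocessing import DegenerateInputError
from .simulate import SignalChannel
from .surrogates import SurrogateWaveform

__all__ = [
    "WindowMetrics",
    "VALIDITY_THRESHOLD",
    "valid_window",
    "smooth_waveform",
    "find_breath_extrema",
    "compute_window_metrics",
    "metrics_from_waveform",
]

VALIDITY_THRESHOLD = 0.6
#: Maximum plausible breathing rate (breaths/min) -> minimum peak spacing.
MAX_BREATH_RATE_BPM = 36.0


@dataclass(frozen=True)
class WindowMetrics:
    """Window-averaged breathing metrics plus validity bookkeeping."""

    tinsp_s: float
    texp_s: float
    ibi_s: float
    br_bpm: float
    ie_ratio: float
    valid: bool
    pearson_r: float
    n_breaths: int


def valid_window(derived: SurrogateWaveform | np.ndarray,
                 reference: SignalChannel | np.ndarray,
                 threshold: float = VALIDITY_THRESHOLD) -> tuple[bool, float]:
    """Pearson-correlation validity screen (boundary inclusive: r >= threshold)."""
    d = derived.samples if hasattr(derived, "samples") else np.asarray(derived, float)
    r_ = reference.samples if hasattr(reference, "samples") else np.asarray(reference, float)
    if d.size != r_.size or d.size < 3:
        raise ValueError("derived and reference must have equal length >= 3")
    if np.std(d) == 0 or np.std(r_) == 0:
        raise DegenerateInputError("zero-variance input to validity check")
    r = float(pearsonr(d, r_).statistic)
    return r >= threshold, r


def smooth_waveform(w: SurrogateWaveform, window_s: float = 2.04,
                    polyorder: int = 3) -> SurrogateWaveform:
    """Savitzky-Golay smoothing (default 51 samples at 25 Hz, cubic)."""
    length = int(round(window_s * w.rate_hz))
    if length % 2 == 0:
        length += 1
    if length <= polyorder:
        raise ValueError("smoothing window too short for the polynomial order")
    if length > len(w):
        raise ValueError("smoothing window longer than the waveform")
    return replace(w, samples=savgol_filter(w.samples, length, polyorder))


def find_breath_extrema(tvw: SignalChannel | np.ndarray,
                        rate_hz: float | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Respiratory peaks and the global-minimum trough between each pair.

    Peaks must be at least 60/36 s apart (max plausible breathing rate)
    and prominent relative to the waveform's spread.
    """
    if hasattr(tvw, "samples"):
        x, fs = tvw.samples, tvw.rate_hz
    else:
        x = np.asarray(tvw, float)
        if rate_hz is None:
            raise ValueError("rate_hz required for a bare array")
        fs = rate_hz
    if x.size < 3:
        raise ValueError("waveform too short")
    min_dist = max(1, int(round(60.0 / MAX_BREATH_RATE_BPM * fs)))
    prominence = 0.5 * float(np.std(x))
    # pad with the global minimum so breaths truncated at the window
    # edges keep their full prominence
    xp = np.concatenate([[x.min()], x, [x.min()]])
    peaks, _ = find_peaks(xp, distance=min_dist, prominence=prominence)
    peaks = peaks - 1
    # a boundary sample is never a genuine breath apex
    peaks = peaks[(peaks > 0) & (peaks < x.size - 1)]
    troughs = np.empty(max(peaks.size - 1, 0), dtype=int)
    for i in range(peaks.size - 1):
        a, b = peaks[i] + 1, peaks[i + 1]
        troughs[i] = a + int(np.argmin(x[a:b]))
    return peaks, troughs


def compute_window_metrics(peaks: np.ndarray, troughs: np.ndarray,
                           rate_hz: float, pearson_r: float = np.nan,
                           valid: bool = True) -> WindowMetrics:
    """Window-averaged metrics from breath extrema.

    IBI averages consecutive-peak gaps; Tinsp averages trough-to-next-
    peak gaps; Texp averages peak-to-next-trough gaps.  The I:E ratio
    averages per-breath Tinsp_i / Texp_i over consecutive inspiration/
    expiration pairs (falling back to the ratio of means when no full
    pair fits the window); partial breaths at the edges are dropped.
    """
    peaks = np.asarray(peaks, dtype=int)
    troughs = np.asarray(troughs, dtype=int)
    if peaks.size < 2:
        raise ValueError("need at least 2 peaks to compute breathing metrics")
    if troughs.size != peaks.size - 1:
        raise ValueError("expected one trough between consecutive peaks")
    ibi = float(np.mean(np.diff(peaks))) / rate_hz
    tinsp_all = (peaks[1:] - troughs) / rate_hz
    texp_all = (troughs - peaks[:-1]) / rate_hz
    tinsp = float(np.mean(tinsp_all))
    texp = float(np.mean(texp_all))
    # Pair each inspiration with the immediately following expiration.
    ratios = [tinsp_all[i] / texp_all[i + 1]
              for i in range(len(troughs) - 1) if texp_all[i + 1] > 0]
    if ratios:
        ie = float(np.mean(ratios))
    elif texp > 0:
        ie = tinsp / texp
    else:
        raise ValueError("degenerate extrema: zero expiration time")
    return WindowMetrics(
        tinsp_s=tinsp, texp_s=texp, ibi_s=ibi, br_bpm=60.0 / ibi,
        ie_ratio=ie, valid=valid, pearson_r=float(pearson_r),
        n_breaths=int(peaks.size - 1),
    )


def metrics_from_waveform(derived: SurrogateWaveform,
                          reference: SignalChannel,
                          threshold: float = VALIDITY_THRESHOLD,
                          smooth: bool | None = None) -> WindowMetrics | None:
    """Validity screen + extrema extraction + window metrics in one call.

    Smoothing defaults to on for X_LSTM waveforms only.  Returns None
    when the window is invalid or has fewer than two detectable breaths.
    """
    valid, r = valid_window(derived, reference, threshold)
    if not valid:
        return None
    if smooth is None:
        smooth = derived.method_id == "X_LSTM"
    w = smooth_waveform(derived) if smooth else derived
    peaks, troughs = find_breath_extrema(w.samples, w.rate_hz)
    if peaks.size < 2:
        return None
    return compute_window_metrics(peaks, troughs, w.rate_hz, pearson_r=r)
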