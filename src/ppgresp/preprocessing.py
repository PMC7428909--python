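"""Feature construction: aligned, normalized 25 Hz windows.

All four model features (raw PPG, narrowly bandpassed PPG, SpO2, pulse
rate) and the reference RTV target are brought to a common 25 Hz time
base, normalized to [-1, +1] per recording, and cut into 1000-sample
(40 s) windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt, sos2zpk

from .simulate import PhysioRecording, SignalChannel

__all__ = [
    "FeatureWindow",
    "FEATURE_RATE_HZ",
    "WINDOW_SAMPLES",
    "resample_channel",
    "normalize_pm1",
    "bandpass_ppg_feature",
    "build_feature_windows",
]

FEATURE_RATE_HZ = 25.0
WINDOW_SAMPLES = 1000  # 40 s at 25 Hz

FEATURE_NAMES = ("ppg", "ppg_bandpassed", "spo2", "pulse_rate")


class DegenerateInputError(ValueError):
    """Raised for inputs on which an operation is mathematically undefined."""


@dataclass(frozen=True)
class FeatureWindow:
    """A 4 x 1000 feature block (25 Hz) with its aligned RTV target.

    Rows: PPG, bandpassed PPG, SpO2, pulse rate; all values in [-1, 1]
    after per-recording normalization.
    """

    features: np.ndarray
    target: np.ndarray
    window_index: int
    subject_id: str
    prescribed_rate_bpm: float
    start_sample: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        t = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "target", t)
        if f.ndim != 2 or f.shape[0] != len(FEATURE_NAMES):
            raise ValueError("features must be a 4 x n matrix")
        if t.shape != (f.shape[1],):
            raise ValueError("target length must match feature columns")


def resample_channel(channel: SignalChannel, target_rate: float) -> SignalChannel:
    """Polyphase (anti-aliased) resampling to ``target_rate``.

    The channel mean is removed before filtering and restored afterwards
    so DC is preserved exactly for constant inputs.
    """
    if len(channel) == 0:
        raise ValueError("cannot resample an empty channel")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    ratio = Fraction(target_rate / channel.rate_hz).limit_denominator(1000)
    if ratio == 1:
        return SignalChannel(channel.samples.copy(), target_rate)
    mean = channel.samples.mean()
    out = resample_poly(channel.samples - mean, ratio.numerator, ratio.denominator,
                        padtype="line")
    return SignalChannel(out + mean, target_rate)


def normalize_pm1(x: np.ndarray) -> np.ndarray:
    """Affine map sending min(x) to -1 and max(x) to +1."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateInputError("cannot normalize a constant sequence to [-1, 1]")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def design_respiratory_bandpass(center_hz: float, rate_hz: float,
                                bandwidth_hz: float = 0.002) -> np.ndarray:
    """Order-6 Butterworth bandpass (cascaded second-order sections).

    The 0.002 Hz passband centred on the breathing frequency is
    near-singular at 25 Hz sampling; the design is returned in SOS form
    and verified stable (all poles strictly inside the unit circle).
    """
    nyq = rate_hz / 2.0
    if not 0 < center_hz < nyq:
        raise ValueError(f"center frequency must lie in (0, {nyq}) Hz")
    lo = center_hz - bandwidth_hz / 2.0
    hi = center_hz + bandwidth_hz / 2.0
    if lo <= 0:
        raise ValueError("passband lower edge must be positive")
    sos = butter(3, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    _, poles, _ = sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise RuntimeError("unstable bandpass design")  # pragma: no cover
    return sos


def bandpass_ppg_feature(ppg25: SignalChannel, resp_rate_hz: float) -> SignalChannel:
    """Zero-phase narrowband PPG feature centred on the breathing frequency."""
    sos = design_respiratory_bandpass(resp_rate_hz, ppg25.rate_hz)
    out = sosfiltfilt(sos, ppg25.samples)
    return SignalChannel(out, ppg25.rate_hz)


def _resample_to_feature_rate(rec: PhysioRecording) -> dict[str, np.ndarray]:
    ppg25 = resample_channel(rec.ppg, FEATURE_RATE_HZ)
    bp25 = bandpass_ppg_feature(ppg25, rec.prescribed_rate_bpm / 60.0)
    spo2_25 = resample_channel(rec.spo2, FEATURE_RATE_HZ)
    pr25 = resample_channel(rec.pulse_rate, FEATURE_RATE_HZ)
    rtv25 = resample_channel(rec.rtv, FEATURE_RATE_HZ)
    n = min(len(ppg25), len(bp25), len(spo2_25), len(pr25), len(rtv25))
    return {
        "ppg": ppg25.samples[:n],
        "ppg_bandpassed": bp25.samples[:n],
        "spo2": spo2_25.samples[:n],
        "pulse_rate": pr25.samples[:n],
        "rtv": rtv25.samples[:n],
    }


def build_feature_windows(
    recording: PhysioRecording,
    window_samples: int = WINDOW_SAMPLES,
    stride_samples: int | None = None,
) -> list[FeatureWindow]:
    """Resample, normalize (per recording) and window one serial.

    The bandpass feature is centred on the serial's prescribed breathing
    rate, mirroring the ground-truth-centred filter of the protocol.
    Trailing partial windows are dropped.
    """
    if stride_samples is None:
        stride_samples = window_samples
    if window_samples < 2 or stride_samples < 1:
        raise ValueError("window_samples >= 2 and stride_samples >= 1 required")
    tracks = _resample_to_feature_rate(recording)
    n = len(tracks["rtv"])
    if n < window_samples:
        raise ValueError(
            f"recording has {n} samples at {FEATURE_RATE_HZ:g} Hz; "
            f"need at least {window_samples}"
        )
    normed = {name: normalize_pm1(x) for name, x in tracks.items()}
    features = np.vstack([normed[name] for name in FEATURE_NAMES])
    target = normed["rtv"]

    windows: list[FeatureWindow] = []
    for idx, start in enumerate(range(0, n - window_samples + 1, stride_samples)):
        sl = slice(start, start + window_samples)
        windows.append(
            FeatureWindow(
                features=features[:, sl].copy(),
                target=target[sl].copy(),
                window_index=idx,
                subject_id=recording.subject_id,
                prescribed_rate_bpm=recording.prescribed_rate_bpm,
                start_sample=start,
            )
        )
    return windows
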