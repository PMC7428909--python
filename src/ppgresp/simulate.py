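"""Synthetic controlled-breathing physiological recordings.

The study design this module emulates: subjects breathe at a prescribed,
metronome-paced rate (6-14 breaths/min) while a finger pulse oximeter
records a PPG (75 Hz) plus SpO2 and pulse-rate summaries (3 Hz), and
respiratory inductance bands provide a reference relative tidal volume
(RTV) signal at 100 Hz.  Respiration leaves three well-known imprints on
the PPG: amplitude modulation of the pulses (AM), baseline wander (BW),
and respiratory sinus arrhythmia, i.e. beat-to-beat frequency modulation
(FM).  The simulator synthesizes a pulse train carrying all three
modulations from a shared respiratory waveform, so every downstream
extraction method has a known ground truth to be measured against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SignalChannel",
    "SimulationConfig",
    "PhysioRecording",
    "simulate_respiratory_waveform",
    "simulate_recording",
    "simulate_cohort",
    "STUDY_RATES_BPM",
]

#: Prescribed breathing rates used in the controlled-breathing protocol.
STUDY_RATES_BPM = (6, 8, 10, 12, 14)

PPG_RATE_HZ = 75.0
AUX_RATE_HZ = 3.0
RTV_RATE_HZ = 100.0


@dataclass(frozen=True)
class SignalChannel:
    """A uniformly sampled scalar time series.

    Sample index 0 is t = 0; timestamps are seconds from recording start.
    """

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("SignalChannel samples must be one-dimensional")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated controlled-breathing serial.

    Modulation depths are expressed as fractions of the (unit) pulse
    amplitude; ``fm_depth`` is the fractional swing of the beat interval
    (respiratory sinus arrhythmia).  ``drift_amplitude`` adds band-limited
    non-respiratory baseline wander (vasomotor / Mayer-wave band) which
    real finger PPG exhibits; it is off by default.
    """

    duration_s: float = 300.0
    breathing_rate_bpm: float = 10.0
    ie_ratio: float = 1.0
    heart_rate_bpm: float = 65.0
    am_depth: float = 0.2
    bw_amplitude: float = 0.15
    fm_depth: float = 0.05
    noise_sd: float = 0.0
    spo2_baseline: float = 97.0
    drift_amplitude: float = 0.0
    seed: int = 0
    # Per-subject pulse-template shape (systolic/dicrotic lobe geometry).
    systolic_width: float = 0.11
    dicrotic_delay: float = 0.55
    dicrotic_amplitude: float = 0.45

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.breathing_rate_bpm <= 0:
            raise ValueError("breathing_rate_bpm must be positive")
        if self.ie_ratio <= 0:
            raise ValueError("ie_ratio must be positive")
        if self.heart_rate_bpm <= self.breathing_rate_bpm:
            raise ValueError("heart_rate_bpm must exceed breathing_rate_bpm")
        for name in ("am_depth", "bw_amplitude", "fm_depth", "noise_sd"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1); got {v}")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be non-negative")


@dataclass(frozen=True)
class PhysioRecording:
    """One subject/serial: PPG, SpO2, pulse rate and reference RTV."""

    ppg: SignalChannel
    spo2: SignalChannel
    pulse_rate: SignalChannel
    rtv: SignalChannel
    subject_id: str
    prescribed_rate_bpm: float
    config: SimulationConfig | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        expected = {
            "ppg": PPG_RATE_HZ,
            "spo2": AUX_RATE_HZ,
            "pulse_rate": AUX_RATE_HZ,
            "rtv": RTV_RATE_HZ,
        }
        for name, rate in expected.items():
            ch: SignalChannel = getattr(self, name)
            if abs(ch.rate_hz - rate) > 1e-9:
                raise ValueError(f"{name} channel must be sampled at {rate} Hz")
        durations = [self.ppg.duration_s, self.spo2.duration_s,
                     self.pulse_rate.duration_s, self.rtv.duration_s]
        # All channels must span the same interval to within one (coarsest)
        # sample period.
        if max(durations) - min(durations) > 1.0 / AUX_RATE_HZ + 1e-9:
            raise ValueError("channels do not span the same time interval")


def simulate_respiratory_waveform(config: SimulationConfig) -> SignalChannel:
    """Reference relative-tidal-volume waveform at 100 Hz.

    Each breath cycle is piecewise raised-cosine: a rise (inspiration)
    lasting ``IBI * IE / (1 + IE)`` followed by a fall (expiration)
    lasting ``IBI / (1 + IE)``, so asymmetric I:E ratios are
    representable.  Peak-to-peak amplitude is 1; the signal starts at a
    trough (end-expiration) at t = 0.
    """
    ibi = 60.0 / config.breathing_rate_bpm
    tinsp = ibi * config.ie_ratio / (1.0 + config.ie_ratio)
    texp = ibi / (1.0 + config.ie_ratio)
    n = int(round(config.duration_s * RTV_RATE_HZ))
    t = np.arange(n) / RTV_RATE_HZ
    phase = np.mod(t, ibi)
    rising = phase < tinsp
    w = np.empty(n)
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * phase[rising] / tinsp))
    w[~rising] = 0.5 * (1.0 + np.cos(np.pi * (phase[~rising] - tinsp) / texp))
    return SignalChannel(w, RTV_RATE_HZ)


def _pulse_template(tau: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Fixed asymmetric two-lobe pulse shape on normalized beat time tau in [0, 1)."""
    systolic = np.exp(-0.5 * ((tau - 0.25) / config.systolic_width) ** 2)
    dicrotic = config.dicrotic_amplitude * np.exp(
        -0.5 * ((tau - config.dicrotic_delay) / 0.18) ** 2
    )
    return systolic + dicrotic


def _respiratory_drive(config: SimulationConfig) -> tuple[np.ndarray, SignalChannel]:
    """Mean-removed, unit-peak respiratory signal r(t) on the 100 Hz grid."""
    rtv = simulate_respiratory_waveform(config)
    r = rtv.samples - rtv.samples.mean()
    peak = np.max(np.abs(r))
    if peak > 0:
        r = r / peak
    return r, rtv


def _sample_drive(r100: np.ndarray, t: np.ndarray) -> np.ndarray:
    t100 = np.arange(r100.size) / RTV_RATE_HZ
    return np.interp(t, t100, r100)


def _vasomotor_drift(n: int, rate_hz: float, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Band-limited (~0.01-0.15 Hz) non-respiratory baseline wander."""
    if amplitude == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    nyq = rate_hz / 2.0
    sos = butter(2, [0.01 / nyq, 0.15 / nyq], btype="bandpass", output="sos")
    drift = sosfiltfilt(sos, white)
    sd = drift.std()
    if sd > 0:
        drift = drift / sd * amplitude
    return drift


def simulate_recording(config: SimulationConfig) -> PhysioRecording:
    """Simulate one controlled-breathing serial.

    The PPG is a train of two-lobe pulses whose per-beat amplitude is
    scaled by ``1 + am_depth * r(t)``, whose baseline carries
    ``bw_amplitude * r(t)`` (plus optional vasomotor drift), and whose
    beat-to-beat interval is ``(60/HR) * (1 - fm_depth * r(t))``, where
    r(t) is the mean-removed, unit-peak respiratory waveform.  Gaussian
    noise of standard deviation ``noise_sd`` is added to the PPG.
    """
    if config.fm_depth >= 1:
        raise ValueError("fm_depth >= 1 can produce non-positive beat intervals")
    rng = np.random.default_rng(config.seed)
    r100, rtv = _respiratory_drive(config)

    base_interval = 60.0 / config.heart_rate_bpm
    beat_times: list[float] = []
    beat_intervals: list[float] = []
    t = 0.0
    while t < config.duration_s:
        drive = _sample_drive(r100, np.array([t]))[0]
        interval = base_interval * (1.0 - config.fm_depth * drive)
        beat_times.append(t)
        beat_intervals.append(interval)
        t += interval
    beat_times_arr = np.asarray(beat_times)
    beat_intervals_arr = np.asarray(beat_intervals)

    n_ppg = int(round(config.duration_s * PPG_RATE_HZ))
    t_ppg = np.arange(n_ppg) / PPG_RATE_HZ
    ppg = np.zeros(n_ppg)
    amp = 1.0 + config.am_depth * _sample_drive(r100, beat_times_arr)
    for tk, Tk, ak in zip(beat_times_arr, beat_intervals_arr, amp):
        i0 = int(np.ceil(tk * PPG_RATE_HZ))
        i1 = min(int(np.ceil((tk + Tk) * PPG_RATE_HZ)), n_ppg)
        if i0 >= i1:
            continue
        tau = (t_ppg[i0:i1] - tk) / Tk
        ppg[i0:i1] += ak * _pulse_template(tau, config)

    ppg += config.bw_amplitude * _sample_drive(r100, t_ppg)
    ppg += _vasomotor_drift(n_ppg, PPG_RATE_HZ, config.drift_amplitude, rng)
    if config.noise_sd > 0:
        ppg += rng.normal(0.0, config.noise_sd, size=n_ppg)

    n_aux = int(round(config.duration_s * AUX_RATE_HZ))
    t_aux = np.arange(n_aux) / AUX_RATE_HZ
    inst_rate = 60.0 / beat_intervals_arr
    pulse_rate = np.interp(t_aux, beat_times_arr, inst_rate)
    # SpO2: baseline plus a small (<1%) respiratory oscillation.
    spo2 = config.spo2_baseline + 0.4 * _sample_drive(r100, t_aux)

    return PhysioRecording(
        ppg=SignalChannel(ppg, PPG_RATE_HZ),
        spo2=SignalChannel(spo2, AUX_RATE_HZ),
        pulse_rate=SignalChannel(pulse_rate, AUX_RATE_HZ),
        rtv=rtv,
        subject_id="sim",
        prescribed_rate_bpm=config.breathing_rate_bpm,
        config=config,
    )


def simulate_cohort(
    n_subjects: int = 9,
    rates_bpm: tuple[float, ...] = STUDY_RATES_BPM,
    duration_s: float = 300.0,
    seed: int = 1,
    noise_sd: float = 0.05,
    drift_amplitude: float = 0.15,
) -> list[PhysioRecording]:
    """Simulate the study cohort: ``n_subjects`` x one serial per rate.

    Per-subject physiology (heart rate, modulation depths, pulse template
    geometry, SpO2 baseline) is drawn once per subject; the I:E ratio and
    small modulation-depth jitter vary per serial, so cross-validation
    folds see genuine inter-serial variation.  All randomness derives
    from ``seed``; serial seeds stay below 2**31.
    """
    recordings: list[PhysioRecording] = []
    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(n_subjects)
    for s, seq in enumerate(subject_seqs):
        rng = np.random.default_rng(seq)
        hr = rng.uniform(55.0, 80.0)
        am = rng.uniform(0.15, 0.35)
        bw = rng.uniform(0.10, 0.30)
        fm = rng.uniform(0.03, 0.10)
        spo2 = rng.uniform(96.0, 99.0)
        sys_w = rng.uniform(0.09, 0.13)
        dic_d = rng.uniform(0.50, 0.62)
        dic_a = rng.uniform(0.30, 0.55)
        for j, rate in enumerate(rates_bpm):
            serial_seed = int(rng.integers(0, 2**31 - 1))
            cfg = SimulationConfig(
                duration_s=duration_s,
                breathing_rate_bpm=rate,
                ie_ratio=rng.uniform(0.8, 1.25),
                heart_rate_bpm=hr,
                am_depth=float(np.clip(am + rng.uniform(-0.05, 0.05), 0.0, 0.99)),
                bw_amplitude=float(np.clip(bw + rng.uniform(-0.05, 0.05), 0.0, 0.99)),
                fm_depth=fm,
                noise_sd=noise_sd,
                spo2_baseline=spo2,
                drift_amplitude=drift_amplitude,
                seed=serial_seed,
                systolic_width=sys_w,
                dicrotic_delay=dic_d,
                dicrotic_amplitude=dic_a,
            )
            rec = simulate_recording(cfg)
            rec = replace(rec, subject_id=f"S{s + 1:02d}")
            recordings.append(rec)
    return recordings
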