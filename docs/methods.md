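# Methods

This note documents the models, parameters and numerical choices behind
`ppgresp`, in the spirit of a methods appendix: what is simulated, how
each derivation works, which knobs matter, and what the synthetic
results do and do not demonstrate.

## The synthetic cohort

The package targets a controlled-breathing protocol — subjects at rest
pace their breathing to a metronome at 6, 8, 10, 12 or 14 breaths/min
for a few minutes per rate while a finger pulse oximeter records a PPG
(75 Hz) with SpO2 and pulse-rate summaries (3 Hz), and respiratory
inductance bands provide a reference relative-tidal-volume (RTV) signal
(100 Hz).  No such dataset is publicly deposited, so the simulator
stands in for it and every quantitative result in this repository is a
property of simulated, not human, data.

**Respiratory waveform.**  Each breath cycle is piecewise raised-cosine:
a rise of duration `IBI · IE / (1 + IE)` (inspiration) and a fall of
`IBI / (1 + IE)` (expiration), peak-to-peak amplitude 1.  A plain
sinusoid cannot represent `I:E ≠ 1`; the raised-cosine pair keeps the
waveform smooth at the joins while making inspiration/expiration
asymmetry expressible.

**PPG.**  A train of stereotyped two-lobe pulses (Gaussian systolic lobe
at 25% of the beat, dicrotic shoulder near 55%, shape jittered per
subject) is modulated by the mean-removed, unit-peak respiratory drive
`r(t)`: per-beat amplitude `1 + am_depth · r(t)`, additive baseline
`bw_amplitude · r(t)`, and beat interval `(60/HR) · (1 − fm_depth ·
r(t))`.  White Gaussian noise (`noise_sd`) and band-limited
non-respiratory baseline wander (`drift_amplitude`, 0.01–0.15 Hz,
emulating vasomotor/Mayer-wave activity) complete the signal.  The
drift term exists because real finger PPG always carries low-frequency
wander that is *not* respiration; without it, any wideband respiratory
filter would trivially succeed on synthetic data.  SpO2 and pulse rate
are smooth low-rate summaries (baseline plus a <1% respiratory
oscillation; interpolated instantaneous beat rate) rather than
physiological models — they serve only as auxiliary model inputs.

**Cohort defaults.**  Per subject, drawn once from the seeded generator:
heart rate U(55, 80) beats/min, AM depth U(0.15, 0.35), BW amplitude
U(0.10, 0.30), FM depth U(0.03, 0.10), SpO2 baseline U(96, 99)%, and
pulse-template geometry jitter; per serial: I:E U(0.8, 1.25) and small
modulation-depth jitter.  Fixed across the cohort: `noise_sd = 0.05`,
`drift_amplitude = 0.15` (both as fractions of unit pulse amplitude).
These sit in the ranges reported for resting finger PPG — respiratory
AM and baseline wander are minority components of the pulse amplitude,
respiratory sinus arrhythmia is a few percent of the beat interval at
these ages — and give every classical method genuine signal to find
(the AM-recoverability property in the test suite checks this floor).
All randomness flows from a single root seed through
`numpy.random.SeedSequence` spawning, so cohorts are bit-reproducible.

**What the simulator omits:** motion artifacts, apnea and irregular
breathing, SpO2 desaturation, arrhythmia, sensor dropouts, and genuine
decoupling between pulse and respiration.  Consequences below.

## Preprocessing

All channels are polyphase-resampled (anti-aliased, DC-exact) to 25 Hz,
normalized per recording by the affine map sending the recording
minimum/maximum to −1/+1, and cut into 1000-sample (40 s) windows.  The
fourth model feature is the PPG passed through a 6th-order Butterworth
bandpass of width 0.002 Hz centred on the serial's *prescribed*
breathing frequency — the protocol's ground-truth rate, deliberately so
(a deployment system would substitute an estimated rate; the
`bandpass_ppg_feature` center is a free argument).  At 25 Hz sampling a
0.002 Hz passband is numerically near-singular in transfer-function
form, so the filter is designed and applied as cascaded second-order
sections, verified stable at construction, and applied forward–backward
(zero phase) to avoid lag between the feature and the target.  Note the
physics: a filter this narrow has an impulse response of order
1/bandwidth ≈ 500–1000 s, so on minutes-long serials its output is
dominated by the in-band respiratory line — which is exactly its
purpose as a feature.

## Classical surrogate methods

Filter-based: `X_A1` bandpasses the PPG over a plausible respiratory
band, taken as 4–36 breaths/min (0.067–0.6 Hz), covering the study's
6–14 breaths/min with margin.  `X_A2`/`X_A3` compute the
continuous wavelet transform (analytic Morlet, `cmor1.5-1.0`, 40
log-spaced pseudo-frequencies over 0.5–3.667 Hz = 30–220 beats/min) and
take, per time step, the maximum cardiac-band magnitude (`X_A2`) or the
pseudo-frequency attaining it (`X_A3`).

Feature-based methods need beat annotations: pulse peaks are local
maxima at least 60/220 s apart whose prominence exceeds 0.3 × the
rolling signal spread over 10 s (scale-free under ±1 normalization);
each trough is the global minimum between flanking peaks; pulse width
uses a 50% fractional-amplitude wave-boundary rule (the
intersecting-tangent alternative is not implemented).  The per-beat
series — mean of trough and following peak (`X_B1`), their difference
(`X_B2`), trough-to-trough interval (`X_B3`), mean level between
troughs (`X_B4`), peak amplitude (`X_B5`), trough amplitude (`X_B6`),
pulse width (`X_B10`; identifiers B7–B9 are a numbering gap inherited
from the field's method table) — is cubic-spline interpolated from beat
anchor times to a uniform 25 Hz grid, holding edge values.

Before comparison, each surrogate window is shifted by the lag
(|lag| ≤ 10 s) maximizing overlap-normalized cross-correlation with the
reference; the normalization matters because unnormalized correlation
biases the argmax toward zero lag for slowly varying signals.

## The sequence model

`LSTMRespirationRegressor`: 2 stacked LSTM layers × 16 hidden units,
variational (time-constant) inter-layer dropout at 0.5, and a per-step
linear head; 3473 trainable parameters by the closed form
`Σ_layers 4·(h·(i+h)+h) + (h+1)`.  The architecture is sometimes
described as "300 cells, 2 layers, 16 hidden"; here "cells" is read as
the unrolled sequence length of a training example (300 time steps =
12 s at 25 Hz) since LSTM layers are parameterized by hidden units, not
cell count.  Training: mean squared error between predicted and
reference sequences, Adam at learning rate 0.02, batch 256, gradient
clipping at global norm 5 (a numerical safeguard for the high learning
rate), at most 100 epochs with early stopping when validation MSE fails
to improve for 5 epochs; the best-epoch weights are restored.  Training
examples are dense 300-step slices (stride 100) of the 1000-sample
windows; prediction runs the recurrence over the full window.  The
entire engine is NumPy (vectorized forward pass, full backpropagation
through time); inference is deterministic and the parameter-count
formula is property-tested against enumeration of the weight arrays.

Cross-validation follows the study design: 5 folds stratified by
prescribed breathing rate, each window in exactly one test fold, the
non-test portion split ≈70/15 (of the whole) into train/validation.
Folds rotate *windows*, not subjects — the model sees every subject in
training, matching the protocol being emulated (no claim of
generalization to unseen subjects is made or tested).

## Breathing metrics and agreement

A window is **valid** when Pearson r between derived and reference
waveform is ≥ 0.6 (boundary inclusive; the threshold is a parameter).
LSTM outputs are Savitzky–Golay smoothed before extrema extraction
(window 2.04 s = 51 samples, polyorder 3 — long enough to suppress
sample noise, an order of magnitude shorter than the slowest breath);
classical waveforms are already smooth.  Breath peaks are prominent
maxima at least 60/36 s apart (≤ 36 breaths/min prior, matching the
`X_A1` band); the signal is padded with its minimum so breaths
truncated at window edges keep their prominence, but a boundary sample
itself is never accepted as an apex.  Each trough is the global minimum
strictly between consecutive peaks.  Window metrics average
consecutive-peak gaps (IBI), trough→peak gaps (Tinsp), peak→trough gaps
(Texp); I:E averages per-breath `Tinsp_i / Texp_{i+1-pair}` over
consecutive inspiration/expiration pairs, falling back to the ratio of
means when a 40-s window holds no complete pair.

Agreement per metric/method: Bland–Altman bias and 95% limits
bias ± 1.96·sd(differences) (normal approximation), relative versions
dividing by the pairwise mean, squared Pearson correlation between
derived and reference values, paired t (`mean(d)/(sd(d)/√n)`, dof n−1),
and RMSE.  Only valid windows enter agreement pooling, and pooling is
across all folds (not fold-averaged) except for the BR RMSE, which is
computed per (subject, rate) serial and then averaged.

## Replication problem sizes

The default replication uses 120-s serials (2 min of the protocol's
5-min serials) and a 500-sample window stride, which yields exactly
5 windows per serial × 45 serials = 225 test windows — the same
test-set count as a full-length protocol with non-overlapping windows.
A full run (simulation through 5-fold training and evaluation)
completes in ≈ 8 minutes on one CPU.

## Known limitations

* **Clean data saturates the validity screen.**  With coherent
  modulation, no artifacts and controlled rates, most classical
  methods — not just the learned one — exceed r = 0.6 on nearly every
  window, so valid-window fractions bunch at 100% and the methods
  separate only at stricter thresholds (e.g. r ≥ 0.8).  On real
  recordings the classical methods fail far more often; passing
  synthetic results therefore demonstrate pipeline correctness and
  best-case accuracy, not field performance.
* The reference RTV channel is noise-free, an idealization of
  inductance-band plethysmography.
* The bandpass feature uses the prescribed rate; free-breathing
  deployment would need a rate estimator in its place.
* I:E accuracy degrades fastest of all metrics as waveform shape
  fidelity drops, since it depends on intra-breath timing rather than
  periodicity.
* Pulse-template and modulation models are phenomenological; no
  hemodynamics are simulated, so `X_B10` (pulse width) sees weaker
  respiratory coupling than the amplitude-based features.
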