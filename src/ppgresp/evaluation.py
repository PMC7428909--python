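"""Agreement statistics and the end-to-end replication harness.

Bland-Altman bias and 95% limits of agreement, paired t tests and RMSE
quantify how well each surrogate method's window-averaged breathing
metrics agree with the reference; ``run_replication`` orchestrates the
whole study on the synthetic cohort: simulate, preprocess, extract all
classical surrogates, train the LSTM under k-fold cross-validation,
screen windows for validity, and pool agreement reports per method and
metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import (VALIDITY_THRESHOLD, metrics_from_waveform, valid_window)
from .model import (LSTMRespirationRegressor, TrainingDivergedError,
                    kfold_split, make_training_sequences, windows_to_arrays)
from .preprocessing import DegenerateInputError, build_feature_windows
from .simulate import SignalChannel, simulate_cohort
from .surrogates import (CLASSICAL_METHODS, SurrogateWaveform,
                         align_to_reference, extract_surrogate)
from .beats import detect_beats
from .preprocessing import FEATURE_RATE_HZ, resample_channel

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementReport",
    "ValidityReport",
    "ReplicationConfig",
    "ReplicationResult",
    "bland_altman",
    "paired_t_test",
    "rmse",
    "validity_sweep",
    "run_replication",
]

METRIC_NAMES = ("tinsp_s", "texp_s", "ibi_s", "br_bpm", "ie_ratio")
DEFAULT_SWEEP_THRESHOLDS = (0.0, 0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman + paired-t agreement for one metric/method pair."""

    metric_name: str
    method_id: str
    bias: float
    loa_lower: float
    loa_upper: float
    relative_bias_pct: float
    relative_loa_pct: tuple[float, float]
    r_squared: float
    t_stat: float
    dof: int
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class ValidityReport:
    """Valid-window counts for one method, with a threshold sweep."""

    method_id: str
    n_valid: int
    n_total: int
    threshold_sweep: tuple[tuple[float, int], ...]

    @property
    def fraction(self) -> float:
        return self.n_valid / self.n_total if self.n_total else float("nan")


def bland_altman(derived, reference, metric_name: str = "",
                 method_id: str = "X_LSTM") -> AgreementReport:
    """Bland-Altman agreement between paired derived and reference values.

    Bias is the mean difference (derived - reference); the 95% limits of
    agreement are bias +/- 1.96 sd of the differences.  Relative
    versions divide each difference by the pairwise mean.  ``r_squared``
    is the squared Pearson correlation between the two value sets.
    """
    d = np.asarray(derived, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != r.shape:
        raise ValueError("derived and reference must be paired (equal length)")
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 pairs for limits of agreement")
    diff = d - r
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    denom = 0.5 * (d + r)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * diff / denom
    rel = rel[np.isfinite(rel)]
    if rel.size >= 3:
        rbias = float(rel.mean())
        rsd = float(rel.std(ddof=1))
        rel_loa = (rbias - 1.96 * rsd, rbias + 1.96 * rsd)
    else:
        rbias, rel_loa = float("nan"), (float("nan"), float("nan"))
    if np.std(d) > 0 and np.std(r) > 0:
        r2 = float(stats.pearsonr(d, r).statistic ** 2)
    else:
        r2 = float("nan")
    if sd > 0:
        t, _, p = paired_t_test(d, r)
    else:
        t, p = float("nan"), float("nan")
    return AgreementReport(
        metric_name=metric_name, method_id=method_id, bias=bias,
        loa_lower=loa[0], loa_upper=loa[1], relative_bias_pct=rbias,
        relative_loa_pct=rel_loa, r_squared=r2, t_stat=t, dof=n - 1,
        p_value=p, n_pairs=n,
    )


def paired_t_test(derived, reference) -> tuple[float, int, float]:
    """Two-sided paired t test: t = mean(d) / (sd(d)/sqrt(n)), dof = n-1."""
    d = np.asarray(derived, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != r.shape or d.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    diff = d - r
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance differences: t is undefined")
    n = diff.size
    t = float(diff.mean() / (sd / np.sqrt(n)))
    dof = n - 1
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return t, dof, p


def rmse(y, Y) -> float:
    """Root mean square error between two equal-length sequences."""
    y = np.asarray(y, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if y.shape != Y.shape:
        raise ValueError("sequences must have equal length")
    if y.size == 0:
        raise ValueError("sequences must be non-empty")
    return float(np.sqrt(np.mean((y - Y) ** 2)))


def validity_sweep(r_values, thresholds=DEFAULT_SWEEP_THRESHOLDS,
                   method_id: str = "X_LSTM",
                   validity_threshold: float = VALIDITY_THRESHOLD) -> ValidityReport:
    """Count windows whose r meets each threshold (and the working threshold)."""
    r = np.asarray(r_values, dtype=float)
    sweep = tuple((float(th), int(np.sum(r >= th))) for th in thresholds)
    return ValidityReport(
        method_id=method_id,
        n_valid=int(np.sum(r >= validity_threshold)),
        n_total=int(r.size),
        threshold_sweep=sweep,
    )


# ---------------------------------------------------------------------------
# Replication harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicationConfig:
    """Study conditions for the synthetic replication run."""

    n_subjects: int = 9
    rates_bpm: tuple[float, ...] = (6, 8, 10, 12, 14)
    duration_s: float = 120.0
    window_stride: int = 500
    methods: tuple[str, ...] = CLASSICAL_METHODS
    k_folds: int = 5
    validity_threshold: float = VALIDITY_THRESHOLD
    max_lag_s: float = 10.0
    train_sequence_length: int = 300
    train_sequence_stride: int = 100
    hidden_units: int = 16
    num_layers: int = 2
    dropout_rate: float = 0.5
    learning_rate: float = 0.02
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 5
    seed: int = 1


@dataclass
class ReplicationResult:
    """Everything the study's result tables are built from."""

    window_table: pd.DataFrame
    agreement: list[AgreementReport]
    validity: dict[str, ValidityReport]
    rmse_br_bpm: float
    rmse_br_by_serial: pd.DataFrame
    fold_histories: list[dict] = field(default_factory=list)

    def agreement_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.agreement:
            rows.append({
                "metric": a.metric_name, "method": a.method_id, "bias": a.bias,
                "loa_lower": a.loa_lower, "loa_upper": a.loa_upper,
                "relative_bias_pct": a.relative_bias_pct,
                "relative_loa_lower_pct": a.relative_loa_pct[0],
                "relative_loa_upper_pct": a.relative_loa_pct[1],
                "r_squared": a.r_squared, "t_stat": a.t_stat, "dof": a.dof,
                "p_value": a.p_value, "n_pairs": a.n_pairs,
            })
        return pd.DataFrame(rows)

    def validity_frame(self) -> pd.DataFrame:
        rows = []
        for method, rep in self.validity.items():
            row = {"method": method, "n_valid": rep.n_valid,
                   "n_total": rep.n_total, "fraction": rep.fraction}
            for th, count in rep.threshold_sweep:
                row[f"n_valid_at_{th:g}"] = count
            rows.append(row)
        return pd.DataFrame(rows)


def _window_reference_channel(window) -> SignalChannel:
    return SignalChannel(window.target, FEATURE_RATE_HZ)


def _classical_window_waveforms(recordings, windows_per_rec, methods, max_lag_s):
    """Per-window aligned classical surrogate waveforms.

    Surrogates are extracted once per serial (on the resampled 25 Hz
    PPG), then each test window's slice is aligned to that window's
    reference by bounded cross-correlation.
    """
    out: dict[tuple[int, int, str], SurrogateWaveform] = {}
    for rec_idx, (rec, windows) in enumerate(zip(recordings, windows_per_rec)):
        ppg25 = resample_channel(rec.ppg, FEATURE_RATE_HZ)
        beats = detect_beats(ppg25)
        serial: dict[str, SurrogateWaveform | None] = {}
        for method in methods:
            try:
                serial[method] = extract_surrogate(ppg25, method, beats)
            except ValueError:
                logger.warning("method %s failed on %s", method, rec.subject_id)
                serial[method] = None
        for w in windows:
            ref = _window_reference_channel(w)
            sl = slice(w.start_sample, w.start_sample + len(w.target))
            for method, sur in serial.items():
                if sur is None or len(sur) < sl.stop:
                    continue
                piece = SurrogateWaveform(sur.samples[sl], sur.rate_hz, method)
                if np.std(piece.samples) == 0:
                    continue
                aligned = align_to_reference(piece, ref, max_lag_s)
                out[(rec_idx, w.window_index, method)] = aligned
    return out


def run_replication(config: ReplicationConfig = ReplicationConfig(),
                    out_dir: str | Path | None = None) -> ReplicationResult:
    """Run the full synthetic replication and pool the agreement reports.

    Stages: cohort simulation -> 25 Hz feature windows -> classical
    surrogate extraction with per-window alignment -> k-fold LSTM
    training/prediction (Savitzky-Golay smoothed) -> validity screening
    -> Bland-Altman/paired-t/RMSE pooling over valid windows.
    """
    logger.info("simulating cohort: %d subjects x %s BPM, %.0f s serials",
                config.n_subjects, config.rates_bpm, config.duration_s)
    recordings = simulate_cohort(
        n_subjects=config.n_subjects, rates_bpm=config.rates_bpm,
        duration_s=config.duration_s, seed=config.seed,
    )
    windows_per_rec = [
        build_feature_windows(rec, stride_samples=config.window_stride)
        for rec in recordings
    ]
    all_windows = [w for ws in windows_per_rec for w in ws]
    rec_of_window = [i for i, ws in enumerate(windows_per_rec) for _ in ws]
    logger.info("built %d feature windows", len(all_windows))

    classical = _classical_window_waveforms(
        recordings, windows_per_rec, config.methods, config.max_lag_s)

    folds = kfold_split(all_windows, config.k_folds, config.seed)
    X_all, y_all = windows_to_arrays(all_windows)
    lstm_pred: dict[int, np.ndarray] = {}
    fold_histories: list[dict] = []
    for f, (train_idx, val_idx, test_idx) in enumerate(folds):
        Xtr, ytr = make_training_sequences(
            X_all[train_idx], y_all[train_idx],
            config.train_sequence_length, config.train_sequence_stride)
        Xva, yva = make_training_sequences(
            X_all[val_idx], y_all[val_idx],
            config.train_sequence_length, config.train_sequence_stride)
        est = LSTMRespirationRegressor(
            hidden_units=config.hidden_units, num_layers=config.num_layers,
            dropout_rate=config.dropout_rate,
            learning_rate=config.learning_rate, batch_size=config.batch_size,
            max_epochs=config.max_epochs,
            early_stop_patience=config.early_stop_patience,
            random_state=config.seed + 101 * f,
        )
        # deterministic restart with a fresh init if a fold diverges
        for attempt in range(3):
            try:
                est.fit(Xtr, ytr, X_val=Xva, y_val=yva)
                break
            except TrainingDivergedError:
                if attempt == 2:
                    raise
                logger.warning("fold %d diverged; restarting with new init", f)
                est.set_params(random_state=est.random_state + 1)
        fold_histories.append({"fold": f, **est.history_,
                               "best_epoch": est.best_epoch_,
                               "n_epochs": est.n_epochs_})
        logger.info("fold %d: %d epochs, best val MSE %.4f",
                    f, est.n_epochs_, est.best_val_loss_)
        preds = est.predict(X_all[test_idx])
        for idx, pred in zip(test_idx, preds):
            lstm_pred[int(idx)] = pred

    rows = []
    for widx, window in enumerate(all_windows):
        rec_idx = rec_of_window[widx]
        ref = _window_reference_channel(window)
        ref_metrics = metrics_from_waveform(
            SurrogateWaveform(window.target, FEATURE_RATE_HZ, "X_LSTM"),
            ref, threshold=-1.0, smooth=False)
        candidates: dict[str, SurrogateWaveform] = {}
        if widx in lstm_pred:
            candidates["X_LSTM"] = SurrogateWaveform(
                lstm_pred[widx], FEATURE_RATE_HZ, "X_LSTM")
        for method in config.methods:
            key = (rec_idx, window.window_index, method)
            if key in classical:
                candidates[method] = classical[key]
        for method, waveform in candidates.items():
            try:
                is_valid, r = valid_window(waveform, ref,
                                           threshold=config.validity_threshold)
                m = metrics_from_waveform(
                    waveform, ref, threshold=config.validity_threshold
                ) if is_valid else None
            except DegenerateInputError:
                continue
            row = {
                "window": widx, "subject": window.subject_id,
                "rate_bpm": window.prescribed_rate_bpm, "method": method,
                "pearson_r": r,
                "valid": m is not None,
            }
            if m is not None and ref_metrics is not None:
                for name in METRIC_NAMES:
                    row[name] = getattr(m, name)
                    row[f"ref_{name}"] = getattr(ref_metrics, name)
            rows.append(row)
    table = pd.DataFrame(rows)

    agreement: list[AgreementReport] = []
    validity: dict[str, ValidityReport] = {}
    for method in table["method"].unique():
        sub = table[table["method"] == method]
        validity[method] = validity_sweep(
            sub["pearson_r"].to_numpy(), method_id=method,
            validity_threshold=config.validity_threshold)
        ok = sub[sub["valid"] & sub[f"ref_{METRIC_NAMES[0]}"].notna()] \
            if f"ref_{METRIC_NAMES[0]}" in sub else sub.iloc[0:0]
        if len(ok) >= 3:
            for name in METRIC_NAMES:
                agreement.append(bland_altman(
                    ok[name].to_numpy(), ok[f"ref_{name}"].to_numpy(),
                    metric_name=name, method_id=method))

    lstm_ok = table[(table["method"] == "X_LSTM") & table["valid"]]
    if "br_bpm" in lstm_ok:
        lstm_ok = lstm_ok[lstm_ok["br_bpm"].notna()]
    serial_rows = []
    for (subject, rate), grp in lstm_ok.groupby(["subject", "rate_bpm"]):
        serial_rows.append({
            "subject": subject, "rate_bpm": rate, "n_windows": len(grp),
            "rmse_br": rmse(grp["br_bpm"].to_numpy(),
                            grp["ref_br_bpm"].to_numpy()),
        })
    rmse_by_serial = pd.DataFrame(serial_rows)
    rmse_br = float(rmse_by_serial["rmse_br"].mean()) if len(rmse_by_serial) \
        else float("nan")

    result = ReplicationResult(
        window_table=table, agreement=agreement, validity=validity,
        rmse_br_bpm=rmse_br, rmse_br_by_serial=rmse_by_serial,
        fold_histories=fold_histories,
    )
    if out_dir is not None:
        _write_reports(result, Path(out_dir))
    return result


def _write_reports(result: ReplicationResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.window_table.to_csv(out_dir / "window_metrics.csv", index=False)
    result.agreement_frame().to_csv(out_dir / "agreement.csv", index=False)
    result.validity_frame().to_csv(out_dir / "validity.csv", index=False)
    result.rmse_br_by_serial.to_csv(out_dir / "rmse_br.csv", index=False)
    _bland_altman_plots(result, out_dir)


def _bland_altman_plots(result: ReplicationResult, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lstm = result.window_table
    lstm = lstm[(lstm["method"] == "X_LSTM") & lstm["valid"]]
    if "br_bpm" not in lstm or lstm["br_bpm"].notna().sum() < 3:
        return
    for name in METRIC_NAMES:
        d = lstm[name].to_numpy()
        r = lstm[f"ref_{name}"].to_numpy()
        keep = np.isfinite(d) & np.isfinite(r)
        d, r = d[keep], r[keep]
        if d.size < 3:
            continue
        diff = d - r
        mean = 0.5 * (d + r)
        bias = diff.mean()
        sd = diff.std(ddof=1)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(mean, diff, s=12, alpha=0.6)
        for y, style in ((bias, "-"), (bias + 1.96 * sd, "--"),
                         (bias - 1.96 * sd, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=1)
        ax.set_xlabel(f"mean of derived and reference {name}")
        ax.set_ylabel("derived - reference")
        ax.set_title(f"Bland-Altman: {name} (X_LSTM)")
        fig.tight_layout()
        fig.savefig(out_dir / f"bland_altman_{name}.png", dpi=120)
        plt.close(fig)
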