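"""Recurrent sequence model mapping PPG-derived features to respiration.

A stacked two-layer LSTM with inter-layer dropout and a per-step linear
head regresses the 4-channel, 25 Hz feature stream onto the reference
relative-tidal-volume waveform.  The estimator follows scikit-learn
conventions (``fit``/``predict``, ``get_params``, trailing-underscore
fitted attributes) so it composes with sklearn model selection, while
the underlying network is the package's own NumPy implementation.

Note on naming: the architecture is described elsewhere as "300 cells,
2 layers, 16 hidden"; here "cells" is read as the unrolled sequence
length of a training example (time steps) and "16" as hidden units per
layer, since LSTM layers are parameterized by hidden units.  With these
defaults the closed-form trainable-parameter count is 3473.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold, StratifiedKFold

from . import lstm
from .preprocessing import DegenerateInputError, FeatureWindow

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "TrainingDivergedError",
    "count_trainable_parameters",
    "LSTMRespirationRegressor",
    "kfold_split",
    "windows_to_arrays",
    "make_training_sequences",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of the sequence model."""

    num_layers: int = 2
    hidden_units: int = 16
    sequence_length: int = 300
    dropout_rate: float = 0.5
    input_channels: int = 4

    def __post_init__(self) -> None:
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (Adam, early stopping, cross-validation)."""

    learning_rate: float = 0.02
    batch_size: int = 256
    max_epochs: int = 100
    early_stop_patience: int = 5
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if min(self.batch_size, self.max_epochs, self.early_stop_patience,
               self.k_folds) < 1:
            raise ValueError("batch_size, max_epochs, patience, k_folds must be >= 1")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


def count_trainable_parameters(spec: ModelSpec) -> int:
    """Closed-form parameter count.

    Per LSTM layer with input size i and h hidden units: 4*(h*(i+h)+h)
    weights-plus-biases; the dense head adds h+1.
    """
    total = 0
    i = spec.input_channels
    for _ in range(spec.num_layers):
        total += 4 * (spec.hidden_units * (i + spec.hidden_units) + spec.hidden_units)
        i = spec.hidden_units
    total += spec.hidden_units + 1
    return total


class LSTMRespirationRegressor(BaseEstimator, RegressorMixin):
    """Sequence-to-sequence LSTM regressor (NumPy, CPU).

    Parameters mirror :class:`ModelSpec` and :class:`TrainingConfig`.
    ``fit`` expects ``X`` of shape (n_sequences, n_steps, n_channels)
    and ``y`` of shape (n_sequences, n_steps); an optional validation
    set drives early stopping (patience epochs without improvement
    restore the best-epoch weights).  ``predict`` accepts sequences of
    any length.
    """

    def __init__(self, hidden_units: int = 16, num_layers: int = 2,
                 dropout_rate: float = 0.5, learning_rate: float = 0.02,
                 batch_size: int = 256, max_epochs: int = 100,
                 early_stop_patience: int = 5, clip_norm: float = 5.0,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.num_layers = num_layers
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.clip_norm = clip_norm
        self.random_state = random_state

    # -- scikit-learn plumbing -------------------------------------------
    def _validate_sequences(self, X, y=None, *, fitting: bool):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_sequences, n_steps, n_channels)")
        if not fitting:
            if X.shape[2] != self.n_features_in_:
                raise ValueError(
                    f"X has {X.shape[2]} channels; model was fitted with "
                    f"{self.n_features_in_}")
            return X, None
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape[:2]:
            raise ValueError("y must have shape (n_sequences, n_steps)")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        if float(np.var(y)) == 0.0:
            raise DegenerateInputError("target sequences have zero variance")
        return X, y

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._validate_sequences(X, y, fitting=True)
        self.n_features_in_ = X.shape[2]
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)

        rng = np.random.default_rng(self.random_state)
        params = lstm.init_params(self.n_features_in_, self.hidden_units,
                                  self.num_layers, rng)
        adam = lstm.AdamState(params)
        n = X.shape[0]
        batch = min(self.batch_size, n)
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        keep = 1.0 - self.dropout_rate

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                xb, yb = X[idx], y[idx]
                masks = None
                if self.dropout_rate > 0 and self.num_layers > 1:
                    masks = [
                        (rng.random((xb.shape[0], self.hidden_units)) < keep)
                        / keep
                        for _ in range(self.num_layers - 1)
                    ]
                pred, caches = lstm.forward(xb, params, self.num_layers, masks)
                loss, dY = lstm.mse_loss(pred, yb)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite training loss at epoch {epoch}")
                grads = lstm.backward(dY, caches, params, self.num_layers)
                lstm.clip_gradients(grads, self.clip_norm)
                lstm.adam_step(params, grads, adam, self.learning_rate)
                epoch_losses.append(loss)
            train_loss = float(np.mean(epoch_losses))
            history["train_loss"].append(train_loss)

            if X_val is not None and X_val.shape[0] > 0:
                val_pred = self._predict_params(X_val, params)
                monitor = float(np.mean((val_pred - y_val) ** 2))
            else:
                monitor = train_loss
            history["val_loss"].append(monitor)
            if not np.isfinite(monitor):
                raise TrainingDivergedError(
                    f"non-finite validation loss at epoch {epoch}")
            if monitor < best_loss - 1e-12:
                best_loss = monitor
                best_epoch = epoch
                best_params = {k: v.copy() for k, v in params.items()}
            elif epoch - best_epoch >= self.early_stop_patience:
                break

        self.weights_ = best_params
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_loss)
        self.n_epochs_ = len(history["train_loss"])
        self.n_parameters_ = lstm.n_parameters(best_params)
        return self

    def _predict_params(self, X: np.ndarray, params) -> np.ndarray:
        # Chunk the batch so BPTT-free inference stays memory-bounded.
        outs = []
        for start in range(0, X.shape[0], 512):
            outs.append(lstm.predict(X[start:start + 512], params,
                                     self.num_layers))
        return np.concatenate(outs, axis=0)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")
        X, _ = self._validate_sequences(X, fitting=False)
        return self._predict_params(X, self.weights_)

    def spec(self) -> ModelSpec:
        return ModelSpec(num_layers=self.num_layers,
                         hidden_units=self.hidden_units,
                         dropout_rate=self.dropout_rate,
                         input_channels=getattr(self, "n_features_in_", 4))


def windows_to_arrays(windows: list[FeatureWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature windows into (n, T, 4) inputs and (n, T) targets."""
    X = np.stack([w.features.T for w in windows])
    y = np.stack([w.target for w in windows])
    return X, y


def make_training_sequences(X: np.ndarray, y: np.ndarray,
                            sequence_length: int = 300,
                            stride: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Slice full windows into fixed-length training subsequences.

    Dense striding over each 1000-sample window augments the training
    set the way per-sample sliding windows would, at a fraction of the
    memory.
    """
    n, T, _ = X.shape
    if sequence_length > T:
        raise ValueError("sequence_length exceeds window length")
    starts = range(0, T - sequence_length + 1, stride)
    xs = [X[:, s:s + sequence_length, :] for s in starts]
    ys = [y[:, s:s + sequence_length] for s in starts]
    return np.concatenate(xs, axis=0), np.concatenate(ys, axis=0)


def kfold_split(windows: list[FeatureWindow], k: int, seed: int
                ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """k-fold partitions of windows into (train, validation, test) indices.

    Folds are stratified by prescribed breathing rate where possible so
    every test fold covers all rates; each window appears in exactly one
    test fold, and the non-test portion is split ~70/15 (of the whole)
    into train and validation.
    """
    n = len(windows)
    if k < 2:
        raise ValueError("k must be >= 2 for held-out rotation")
    if n < k:
        raise ValueError(f"need at least {k} windows, got {n}")
    labels = np.array([w.prescribed_rate_bpm for w in windows])
    counts = np.unique(labels, return_counts=True)[1]
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))

    rng = np.random.default_rng(seed)
    folds = []
    for rest, test in split_iter:
        rest = rng.permutation(rest)
        n_val = max(1, int(round(len(rest) * 15.0 / 85.0)))
        val = np.sort(rest[:n_val])
        train = np.sort(rest[n_val:])
        folds.append((train, val, np.sort(test)))
    return folds
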