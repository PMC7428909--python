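"""Sequence model: parameter counts, determinism, folds, training contracts."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from ppgresp import (DegenerateInputError, LSTMRespirationRegressor,
                     ModelSpec, TrainingConfig, count_trainable_parameters,
                     kfold_split, make_training_sequences, windows_to_arrays)
from ppgresp.lstm import init_params, n_parameters
from ppgresp.preprocessing import FeatureWindow


def _fake_windows(n, rates=(6, 8, 10, 12, 14), length=8):
    rng = np.random.default_rng(0)
    return [
        FeatureWindow(features=rng.normal(size=(4, length)),
                      target=rng.normal(size=length),
                      window_index=i, subject_id=f"S{i % 9}",
                      prescribed_rate_bpm=rates[i % len(rates)])
        for i in range(n)
    ]


class TestParameterCount:
    def test_two_layer_reference_count(self):
        spec = ModelSpec(num_layers=2, hidden_units=16, input_channels=4)
        assert count_trainable_parameters(spec) == 3473

    def test_minimal_model_count(self):
        spec = ModelSpec(num_layers=1, hidden_units=1, input_channels=1)
        assert count_trainable_parameters(spec) == 14

    def test_zero_hidden_units_invalid(self):
        with pytest.raises(ValueError):
            ModelSpec(hidden_units=0)

    def test_formula_matches_enumeration_for_random_specs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            layers = int(rng.integers(1, 4))
            hidden = int(rng.integers(1, 40))
            channels = int(rng.integers(1, 8))
            spec = ModelSpec(num_layers=layers, hidden_units=hidden,
                             input_channels=channels)
            params = init_params(channels, hidden, layers,
                                 np.random.default_rng(0))
            assert n_parameters(params) == count_trainable_parameters(spec)


class TestConfigs:
    def test_patience_cannot_exceed_epochs(self):
        with pytest.raises(ValueError):
            TrainingConfig(max_epochs=3, early_stop_patience=5)

    def test_negative_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=-1)

    def test_dropout_bounds(self):
        with pytest.raises(ValueError):
            ModelSpec(dropout_rate=1.0)


class TestEstimatorContracts:
    def test_fitted_count_matches_closed_form(self, small_windows):
        X, y = windows_to_arrays(small_windows[:1])
        est = LSTMRespirationRegressor(max_epochs=1, random_state=0)
        est.fit(X[:, :100, :], y[:, :100])
        assert est.n_parameters_ == count_trainable_parameters(est.spec())

    def test_inference_deterministic_and_shape(self, small_windows):
        X, y = windows_to_arrays(small_windows[:2])
        est = LSTMRespirationRegressor(max_epochs=2, random_state=0)
        est.fit(X[:, :150, :], y[:, :150])
        for T in (50, 300, 1000):
            a = est.predict(X[:, :T, :])
            b = est.predict(X[:, :T, :])
            assert a.shape == (2, T)
            assert np.array_equal(a, b)

    def test_channel_mismatch_rejected(self, small_windows):
        X, y = windows_to_arrays(small_windows[:1])
        est = LSTMRespirationRegressor(max_epochs=1, random_state=0)
        est.fit(X[:, :100, :], y[:, :100])
        with pytest.raises(ValueError):
            est.predict(X[:, :100, :3])

    def test_zero_variance_target_rejected(self, small_windows):
        X, y = windows_to_arrays(small_windows[:1])
        est = LSTMRespirationRegressor(max_epochs=1)
        with pytest.raises(DegenerateInputError):
            est.fit(X[:, :100, :], np.zeros_like(y[:, :100]))

    def test_sklearn_get_set_params_roundtrip(self):
        est = LSTMRespirationRegressor(hidden_units=8)
        params = est.get_params()
        assert params["hidden_units"] == 8
        est.set_params(hidden_units=4)
        assert est.hidden_units == 4


class TestTraining:
    def test_overfits_single_clean_window(self, small_windows):
        X, y = windows_to_arrays(small_windows[:1])
        Xs, ys = make_training_sequences(X, y, 250, 250)
        est = LSTMRespirationRegressor(random_state=0, max_epochs=200,
                                       dropout_rate=0.0, batch_size=4)
        est.fit(Xs, ys)
        pred = est.predict(X)[0]
        assert pearsonr(pred, y[0]).statistic > 0.95

    def test_early_stopping_contract(self, small_windows):
        X, y = windows_to_arrays(small_windows[:3])
        Xs, ys = make_training_sequences(X, y, 200, 200)
        est = LSTMRespirationRegressor(random_state=0, max_epochs=60,
                                       early_stop_patience=3)
        est.fit(Xs[:10], ys[:10], X_val=Xs[10:], y_val=ys[10:])
        # halts no more than patience epochs past the best epoch
        assert est.n_epochs_ <= est.best_epoch_ + est.early_stop_patience + 1
        assert len(est.history_["val_loss"]) == est.n_epochs_

    def test_training_loss_decreases_early(self, small_windows):
        X, y = windows_to_arrays(small_windows)
        Xs, ys = make_training_sequences(X, y, 250, 250)
        est = LSTMRespirationRegressor(random_state=1, max_epochs=4)
        est.fit(Xs, ys)
        losses = est.history_["train_loss"]
        assert losses[3] < losses[0]


class TestBackpropagation:
    def test_gradients_match_finite_differences(self):
        """BPTT gradients against a central-difference oracle."""
        from ppgresp import lstm

        rng = np.random.default_rng(0)
        params = lstm.init_params(3, 4, 2, rng)
        X = rng.normal(size=(2, 7, 3))
        y = rng.normal(size=(2, 7))
        pred, caches = lstm.forward(X, params, 2)
        _, dY = lstm.mse_loss(pred, y)
        grads = lstm.backward(dY, caches, params, 2)
        eps = 1e-6
        for key, p in params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                p[idx] += eps
                up, _ = lstm.mse_loss(lstm.forward(X, params, 2)[0], y)
                p[idx] -= 2 * eps
                down, _ = lstm.mse_loss(lstm.forward(X, params, 2)[0], y)
                p[idx] += eps
                numeric = (up - down) / (2 * eps)
                assert grads[key][idx] == pytest.approx(numeric, abs=1e-7,
                                                        rel=1e-5)


class TestKFold:
    def test_partition_arithmetic(self):
        windows = _fake_windows(225)
        folds = kfold_split(windows, 5, seed=0)
        test_sets = [set(test) for _, _, test in folds]
        assert all(len(t) == 45 for t in test_sets)
        assert set().union(*test_sets) == set(range(225))
        for a in range(5):
            for b in range(a + 1, 5):
                assert not test_sets[a] & test_sets[b]

    def test_fold_isolation_and_coverage(self):
        windows = _fake_windows(50)
        for train, val, test in kfold_split(windows, 5, seed=3):
            assert not set(train) & set(test)
            assert not set(val) & set(test)
            assert not set(train) & set(val)
            # stratified folds: every rate present in each test set
            rates = {windows[i].prescribed_rate_bpm for i in test}
            assert len(rates) == 5

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(_fake_windows(10), 1, seed=0)

    def test_deterministic(self):
        windows = _fake_windows(30)
        a = kfold_split(windows, 5, seed=7)
        b = kfold_split(windows, 5, seed=7)
        for (ta, va, sa), (tb, vb, sb) in zip(a, b):
            assert np.array_equal(ta, tb)
            assert np.array_equal(va, vb)
            assert np.array_equal(sa, sb)
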