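"""Minimal LSTM sequence-regression engine in NumPy.

Implements exactly what the breathing-waveform model needs: stacked
LSTM layers with variational (time-constant) inter-layer dropout, a
per-step linear head, mean-squared-error loss, full backpropagation
through time, and Adam with global-norm gradient clipping.  Weights
live in a flat dict so they can be copied, saved and counted cheaply.

Gate order throughout: input (i), forget (f), candidate (g), output (o).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_params",
    "forward",
    "backward",
    "predict",
    "mse_loss",
    "AdamState",
    "adam_step",
    "clip_gradients",
    "n_parameters",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_params(input_size: int, hidden_size: int, num_layers: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform(-1/sqrt(h), 1/sqrt(h)) init; forget-gate bias starts at +1."""
    params: dict[str, np.ndarray] = {}
    k = 1.0 / np.sqrt(hidden_size)
    for layer in range(num_layers):
        in_size = input_size if layer == 0 else hidden_size
        params[f"Wx{layer}"] = rng.uniform(-k, k, size=(in_size, 4 * hidden_size))
        params[f"Wh{layer}"] = rng.uniform(-k, k, size=(hidden_size, 4 * hidden_size))
        b = rng.uniform(-k, k, size=4 * hidden_size)
        b[hidden_size:2 * hidden_size] += 1.0  # forget-gate bias
        params[f"b{layer}"] = b
    params["Wy"] = rng.uniform(-k, k, size=(hidden_size, 1))
    params["by"] = np.zeros(1)
    return params


def n_parameters(params: dict[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


def _layer_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                   b: np.ndarray) -> tuple[np.ndarray, dict]:
    B, T, _ = X.shape
    H = Wh.shape[0]
    gates = np.empty((T, B, 4 * H))
    Cs = np.empty((T, B, H))
    Hs = np.empty((T, B, H))
    Xw = X @ Wx + b
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        z = Xw[:, t, :] + h @ Wh
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        h = o * np.tanh(c)
        gates[t, :, :H] = i
        gates[t, :, H:2 * H] = f
        gates[t, :, 2 * H:3 * H] = g
        gates[t, :, 3 * H:] = o
        Cs[t] = c
        Hs[t] = h
    cache = {"gates": gates, "Cs": Cs, "Hs": Hs, "X": X}
    return Hs.transpose(1, 0, 2), cache


def forward(X: np.ndarray, params: dict[str, np.ndarray], num_layers: int,
            dropout_masks: list[np.ndarray] | None = None
            ) -> tuple[np.ndarray, list[dict]]:
    """Run the stack on ``X`` of shape (batch, time, channels).

    ``dropout_masks`` (one (batch, hidden) inverted-dropout mask per
    inter-layer gap) are applied identically at every time step
    (variational dropout); ``None`` means inference mode.
    """
    caches: list[dict] = []
    inp = X
    for layer in range(num_layers):
        out, cache = _layer_forward(inp, params[f"Wx{layer}"],
                                    params[f"Wh{layer}"], params[f"b{layer}"])
        if dropout_masks is not None and layer < num_layers - 1:
            mask = dropout_masks[layer]
            cache["dropout_mask"] = mask
            out = out * mask[:, None, :]
        caches.append(cache)
        inp = out
    y = inp @ params["Wy"] + params["by"]
    caches.append({"last_hidden": inp})
    return y[..., 0], caches


def predict(X: np.ndarray, params: dict[str, np.ndarray], num_layers: int
            ) -> np.ndarray:
    """Inference-mode forward pass (dropout inactive)."""
    y, _ = forward(X, params, num_layers, dropout_masks=None)
    return y


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad


def _layer_backward(dH: np.ndarray, cache: dict, Wx: np.ndarray, Wh: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    gates, Cs, Hs, X = cache["gates"], cache["Cs"], cache["Hs"], cache["X"]
    T, B, H = Cs.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.empty_like(X)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = gates[t, :, :H]
        f = gates[t, :, H:2 * H]
        g = gates[t, :, 2 * H:3 * H]
        o = gates[t, :, 3 * H:]
        tc = np.tanh(Cs[t])
        c_prev = Cs[t - 1] if t > 0 else np.zeros((B, H))
        h_prev = Hs[t - 1] if t > 0 else np.zeros((B, H))
        dh = dH[:, t, :] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f),
             dg * (1.0 - g * g), do * o * (1.0 - o)], axis=1)
        dWx += X[:, t, :].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t, :] = dz @ Wx.T
        dh_next = dz @ Wh.T
    return dWx, dWh, db, dX


def backward(dY: np.ndarray, caches: list[dict], params: dict[str, np.ndarray],
             num_layers: int) -> dict[str, np.ndarray]:
    """Gradients of the loss w.r.t. every parameter.

    ``dY`` has shape (batch, time) — the loss gradient at the scalar
    output of every time step.
    """
    grads: dict[str, np.ndarray] = {}
    last_hidden = caches[-1]["last_hidden"]  # (B, T, H)
    dY3 = dY[..., None]
    grads["Wy"] = np.einsum("bth,bto->ho", last_hidden, dY3)
    grads["by"] = dY3.sum(axis=(0, 1))
    dH = dY3 * params["Wy"][None, None, :, 0]
    for layer in range(num_layers - 1, -1, -1):
        cache = caches[layer]
        if "dropout_mask" in cache:
            dH = dH * cache["dropout_mask"][:, None, :]
        dWx, dWh, db, dX = _layer_backward(dH, cache, params[f"Wx{layer}"],
                                           params[f"Wh{layer}"])
        grads[f"Wx{layer}"] = dWx
        grads[f"Wh{layer}"] = dWh
        grads[f"b{layer}"] = db
        dH = dX
    return grads


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float = 5.0) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class AdamState:
    """First/second-moment accumulators for Adam."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0


def adam_step(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
              state: AdamState, lr: float) -> None:
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    bc1 = 1.0 - b1 ** state.t
    bc2 = 1.0 - b2 ** state.t
    for k, p in params.items():
        g = grads[k]
        state.m[k] = b1 * state.m[k] + (1.0 - b1) * g
        state.v[k] = b2 * state.v[k] + (1.0 - b2) * g * g
        m_hat = state.m[k] / bc1
        v_hat = state.v[k] / bc2
        p -= lr * m_hat / (np.sqrt(v_hat) + state.eps)
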