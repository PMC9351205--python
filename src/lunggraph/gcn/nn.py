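"""Minimal NumPy neural-network primitives with explicit backward passes.

Forward functions return a cache consumed by the matching backward
function.  Shapes follow (batch, ..., features); the LSTM works on
(batch, time, features) sequences and returns the final hidden state,
which is how the recurrent neighbor aggregator consumes neighbor
sequences.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# LSTM over a neighbor sequence; hidden size equals input size
# ---------------------------------------------------------------------------


def lstm_init(din: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform(-k, k) init with forget-gate bias 1 (k = 1/sqrt(din))."""
    k = 1.0 / np.sqrt(din)
    b = np.zeros(4 * din)
    b[din : 2 * din] = 1.0
    return {
        "Wx": rng.uniform(-k, k, size=(din, 4 * din)),
        "Wh": rng.uniform(-k, k, size=(din, 4 * din)),
        "b": b,
    }


def lstm_forward(
    X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, list]:
    """Run an LSTM over X (G, T, d); return final hidden state (G, d) + cache."""
    G, T, _ = X.shape
    h = Wh.shape[0]
    hs = np.zeros((G, h))
    cs = np.zeros((G, h))
    cache = []
    for t in range(T):
        z = X[:, t] @ Wx + hs @ Wh + b
        i = sigmoid(z[:, :h])
        f = sigmoid(z[:, h : 2 * h])
        g = np.tanh(z[:, 2 * h : 3 * h])
        o = sigmoid(z[:, 3 * h :])
        c_new = f * cs + i * g
        h_new = o * np.tanh(c_new)
        cache.append((X[:, t], hs, cs, i, f, g, o, c_new))
        hs, cs = h_new, c_new
    return hs, cache


def lstm_backward(
    dh: np.ndarray, cache: list, Wx: np.ndarray, Wh: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backprop through time; returns dX (G, T, d) and parameter gradients."""
    G = dh.shape[0]
    h = Wh.shape[0]
    T = len(cache)
    din = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * h)
    dX = np.zeros((G, T, din))
    dc = np.zeros((G, h))
    for t in reversed(range(T)):
        x_t, h_prev, c_prev, i, f, g, o, c = cache[t]
        tc = np.tanh(c)
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx.T
        dh = dz @ Wh.T
        dc = dc * f
    return dX, {"Wx": dWx, "Wh": dWh, "b": db}


# ---------------------------------------------------------------------------
# Layer normalization over the last axis
# ---------------------------------------------------------------------------

LN_EPS = 1e-5


def layernorm_forward(
    x: np.ndarray, gamma: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, tuple]:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * inv_std
    return xhat * gamma + beta, (xhat, inv_std)


def layernorm_backward(
    dy: np.ndarray, cache: tuple, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, inv_std = cache
    axes = tuple(range(dy.ndim - 1))
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    dxhat = dy * gamma
    dx = inv_std * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# Adam optimizer with optional L2 weight decay on weight matrices
# ---------------------------------------------------------------------------


class Adam:
    def __init__(
        self,
        params: dict[str, np.ndarray],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(
        self,
        params: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
        lr: float,
        weight_decay: float = 0.0,
    ) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            if weight_decay and p.ndim >= 2:  # decay weight matrices only
                g = g + weight_decay * p
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            p -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
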