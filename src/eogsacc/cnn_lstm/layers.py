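"""Minimal NumPy layers with explicit forward/backward passes.

Implemented here rather than pulled from a deep-learning framework so the
classifier runs on a plain scientific-Python stack.  Shapes follow the
(batch, time, channels) convention.  Every layer's ``forward`` returns the
output and a cache; ``backward`` consumes the upstream gradient and the
cache and returns (input gradient, parameter gradients).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot_uniform",
    "conv1d_forward",
    "conv1d_backward",
    "relu_forward",
    "relu_backward",
    "maxpool1d_forward",
    "maxpool1d_backward",
    "lstm_forward",
    "lstm_backward",
    "dropout_forward",
    "dropout_backward",
    "dense_forward",
    "dense_backward",
    "softmax",
    "softmax_crossentropy",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# -- 1-D convolution (valid, stride 1) --------------------------------------


def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x: (N, L, Cin); W: (k, Cin, Cout); b: (Cout,). No padding."""
    k = W.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    # windows: (N, L-k+1, Cin, k) -> move kernel axis next to Cin
    y = np.einsum("nlck,kco->nlo", windows, W, optimize=True) + b
    return y, (x, W)


def conv1d_backward(dy: np.ndarray, cache):
    x, W = cache
    k = W.shape[0]
    L_out = dy.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    dW = np.einsum("nlck,nlo->kco", windows, dy, optimize=True)
    db = dy.sum(axis=(0, 1))
    dx = np.zeros_like(x)
    for j in range(k):
        # y[:, l, o] receives x[:, l+j, c] * W[j, c, o]
        dx[:, j : j + L_out, :] += dy @ W[j].T
    return dx, dW, db


# -- pointwise nonlinearity and pooling -------------------------------------


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0.0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, cache):
    return dy * cache


def maxpool1d_forward(x: np.ndarray, pool: int = 2):
    """Non-overlapping max pooling along time; trailing remainder dropped."""
    n, L, c = x.shape
    L_out = L // pool
    xr = x[:, : L_out * pool, :].reshape(n, L_out, pool, c)
    y = xr.max(axis=2)
    argmax = xr.argmax(axis=2)
    return y, (x.shape, pool, argmax)


def maxpool1d_backward(dy: np.ndarray, cache):
    shape, pool, argmax = cache
    n, L, c = shape
    L_out = dy.shape[1]
    dxr = np.zeros((n, L_out, pool, c), dtype=dy.dtype)
    ni, li, ci = np.ogrid[:n, :L_out, :c]
    dxr[ni, li, argmax, ci] = dy
    dx = np.zeros(shape, dtype=dy.dtype)
    dx[:, : L_out * pool, :] = dxr.reshape(n, L_out * pool, c)
    return dx


# -- LSTM (returns last hidden state) ---------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """x: (N, T, Cin); Wx: (Cin, 4H); Wh: (H, 4H); b: (4H,).

    Gate layout along the last axis is [input, forget, candidate, output].
    Returns the final hidden state h_T of shape (N, H).
    """
    n, T, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    steps = []
    for t in range(T):
        z = x[:, t, :] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_next = f * c + i * g
        tanh_c = np.tanh(c_next)
        h_next = o * tanh_c
        steps.append((h, c, i, f, g, o, tanh_c))
        h, c = h_next, c_next
    return h, (x, Wx, Wh, steps, H)


def lstm_backward(dh_last: np.ndarray, cache):
    x, Wx, Wh, steps, H = cache
    n, T, _ = x.shape
    dx = np.zeros_like(x)
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(Wx.shape[1])
    dh = dh_last
    dc = np.zeros((n, H))
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, tanh_c = steps[t]
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c ** 2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g ** 2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dx[:, t, :] = dz @ Wx.T
        dWx += x[:, t, :].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh = dz @ Wh.T
        dc = dc * f
    return dx, dWx, dWh, db


# -- dropout, dense, softmax -------------------------------------------------


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator | None):
    """Inverted dropout; pass rng=None for inference (identity)."""
    if rng is None or rate <= 0:
        return x, None
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return x * mask, mask


def dropout_backward(dy: np.ndarray, mask):
    return dy if mask is None else dy * mask


def dense_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def dense_backward(dy: np.ndarray, cache, W: np.ndarray):
    x = cache
    return dy @ W.T, x.T @ dy, dy.sum(axis=0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_crossentropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    dlogits = (p - onehot) / n
    return loss, dlogits, p
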