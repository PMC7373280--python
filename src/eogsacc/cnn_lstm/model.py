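"""The saccade classifier: two 1-D conv blocks, an LSTM, dropout, softmax.

Layer order: conv -> ReLU -> maxpool, twice, then LSTM (last hidden
state), dropout, and a dense softmax head with one unit per diagnosis
class.  With the reference configuration (window 192, kernel 3, pool 2,
no padding) the sequence entering the LSTM is 192 -> 190 -> 95 -> 93 ->
46 steps long.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import layers as L

__all__ = ["ModelConfig", "CNNLSTM", "Adam"]


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 192
    conv_filters: int = 128
    kernel_size: int = 3
    pool_size: int = 2
    n_conv_blocks: int = 2
    lstm_units: int = 100
    dropout_rate: float = 0.6
    n_classes: int = 3

    def conv_output_lengths(self) -> list[int]:
        """Sequence length after each conv (valid) and pool stage."""
        lengths = []
        length = self.input_length
        for _ in range(self.n_conv_blocks):
            length = length - (self.kernel_size - 1)
            if length < 1:
                raise ValueError("input too short for the conv/pool stack")
            lengths.append(length)
            length = length // self.pool_size
            if length < 1:
                raise ValueError("input too short for the conv/pool stack")
            lengths.append(length)
        return lengths

    @property
    def lstm_input_length(self) -> int:
        return self.conv_output_lengths()[-1]


class CNNLSTM:
    """NumPy implementation of the conv–recurrent saccade classifier."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        config.conv_output_lengths()  # validates the arithmetic
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        k, f = config.kernel_size, config.conv_filters
        p: dict[str, np.ndarray] = {}
        c_in = 1
        for blk in range(config.n_conv_blocks):
            p[f"conv{blk}_W"] = L.glorot_uniform(rng, (k, c_in, f), k * c_in, k * f)
            p[f"conv{blk}_b"] = np.zeros(f)
            c_in = f
        H = config.lstm_units
        p["lstm_Wx"] = L.glorot_uniform(rng, (c_in, 4 * H), c_in, 4 * H)
        p["lstm_Wh"] = L.glorot_uniform(rng, (H, 4 * H), H, 4 * H)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        p["lstm_b"] = b
        p["dense_W"] = L.glorot_uniform(rng, (H, config.n_classes), H, config.n_classes)
        p["dense_b"] = np.zeros(config.n_classes)
        self.params = p

    # -- parameter plumbing --------------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    # -- forward / backward --------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ):
        """x: (N, 192) or (N, 192, 1). Returns (logits, cache).

        Pass a generator to enable dropout (training mode); ``None`` runs
        inference.
        """
        cfg, p = self.config, self.params
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != cfg.input_length or x.shape[2] != 1:
            raise ValueError(
                f"expected input of shape (n, {cfg.input_length}, 1), got {x.shape}"
            )
        caches = []
        h = x
        for blk in range(cfg.n_conv_blocks):
            h, c_conv = L.conv1d_forward(h, p[f"conv{blk}_W"], p[f"conv{blk}_b"])
            h, c_relu = L.relu_forward(h)
            h, c_pool = L.maxpool1d_forward(h, cfg.pool_size)
            caches.append((c_conv, c_relu, c_pool))
        h, c_lstm = L.lstm_forward(h, p["lstm_Wx"], p["lstm_Wh"], p["lstm_b"])
        h, c_drop = L.dropout_forward(h, cfg.dropout_rate, dropout_rng)
        logits, c_dense = L.dense_forward(h, p["dense_W"], p["dense_b"])
        return logits, (caches, c_lstm, c_drop, c_dense)

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        cfg, p = self.config, self.params
        caches, c_lstm, c_drop, c_dense = cache
        grads: dict[str, np.ndarray] = {}
        dh, grads["dense_W"], grads["dense_b"] = L.dense_backward(
            dlogits, c_dense, p["dense_W"]
        )
        dh = L.dropout_backward(dh, c_drop)
        dh, grads["lstm_Wx"], grads["lstm_Wh"], grads["lstm_b"] = L.lstm_backward(
            dh, c_lstm
        )
        for blk in range(cfg.n_conv_blocks - 1, -1, -1):
            c_conv, c_relu, c_pool = caches[blk]
            dh = L.maxpool1d_backward(dh, c_pool)
            dh = L.relu_backward(dh, c_relu)
            dh, grads[f"conv{blk}_W"], grads[f"conv{blk}_b"] = L.conv1d_backward(
                dh, c_conv
            )
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities, inference mode (no dropout)."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape[0] == 0:
            return np.zeros((0, self.config.n_classes))
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[i : i + batch_size])
            out.append(L.softmax(logits))
        return np.concatenate(out, axis=0)


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
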