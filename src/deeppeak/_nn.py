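"""Minimal 1-D convolutional network engine (numpy).

Forward/backward passes for the small peak-classification network:
stacked (convolution -> ReLU -> max-pool) blocks, an extra max-pool, and
a single-logit dense head, trained with Adam.  Sized for feature vectors
of a few hundred samples and datasets of a few hundred thousand
examples on one CPU; everything is float64 and fully deterministic
given the initialization generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv1D:
    """Same-padded 1-D convolution (cross-correlation), stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_channels * kernel_size))
        self.W = rng.standard_normal((out_channels, in_channels, kernel_size)) * scale
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C, L)
        k = self.W.shape[2]
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        windows = sliding_window_view(xp, k, axis=2)  # (N, C, L, K)
        self._windows = windows
        self._in_shape = x.shape
        return np.einsum("nclk,fck->nfl", windows, self.W, optimize=True) + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        k = self.W.shape[2]
        pad = k // 2
        self.grads[0][...] = np.einsum("nclk,nfl->fck", self._windows, dy, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        # dX: scatter each kernel tap back onto the padded input
        dcols = np.einsum("nfl,fck->nclk", dy, self.W, optimize=True)
        dxp = np.zeros((n, c, length + 2 * pad))
        for t in range(k):
            dxp[:, :, t : t + length] += dcols[:, :, :, t]
        return dxp[:, :, pad : pad + length]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D:
    """Non-overlapping max pooling; an odd trailing sample is dropped."""

    params: list = []
    grads: list = []

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        l2 = length // self.pool
        self._in_length = length
        xv = x[:, :, : l2 * self.pool].reshape(n, c, l2, self.pool)
        self._argmax = xv.argmax(axis=3)
        return xv.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, l2 = dy.shape
        dx = np.zeros((n, c, self._in_length))
        idx = (
            np.arange(n)[:, None, None],
            np.arange(c)[None, :, None],
            np.arange(l2)[None, None, :] * self.pool + self._argmax,
        )
        np.add.at(dx, idx, dy)
        return dx


class Dense:
    """Fully connected layer on flattened input, producing one logit."""

    def __init__(self, in_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.standard_normal((in_features,)) * scale
        self.b = np.zeros(1)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        self._flat = x.reshape(n, -1)
        self._in_shape = x.shape
        return self._flat @ self.W + self.b[0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = dy @ self._flat
        self.grads[1][...] = dy.sum()
        return np.outer(dy, self.W).reshape(self._in_shape)


class ConvNet1D:
    """The peak-classification network: conv blocks + extra pool + dense head."""

    def __init__(self, input_length: int, channels: tuple[int, ...],
                 kernel_size: int, rng: np.random.Generator):
        self.layers: list = []
        length = input_length
        c_in = 1
        for c_out in channels:
            self.layers += [Conv1D(c_in, c_out, kernel_size, rng), ReLU(), MaxPool1D(2)]
            length //= 2
            c_in = c_out
        self.layers.append(MaxPool1D(2))  # the additional pooling layer
        length //= 2
        if length < 1:
            raise ValueError("input too short for this many pooling layers")
        self.layers.append(Dense(c_in * length, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 297) feature vectors -> (N,) logits."""
        h = x[:, None, :]
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def combined_loss_with_logits(
    logits: np.ndarray,
    labels: np.ndarray,
    pos_weight: float,
    alpha: float,
    beta: float,
    gamma: float,
    loss_mix: float,
) -> tuple[float, np.ndarray]:
    """Weighted BCE + focal Tversky loss and its gradient w.r.t. the logits.

    The Tversky index is computed on soft scores over the whole batch:
    TI = TP / (TP + alpha*FN + beta*FP) with TP = sum(p*y),
    FN = sum((1-p)*y), FP = sum(p*(1-y)); the focal term is (1-TI)^gamma.
    Total loss = loss_mix * weighted-BCE + (1 - loss_mix) * focal-Tversky.
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    if z.size == 0:
        raise ValueError("empty batch")
    n = z.size
    w = np.where(y == 1, pos_weight, 1.0)
    p = sigmoid(z)

    # numerically stable BCE with logits
    bce_terms = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    bce = float(np.mean(w * bce_terms))
    dbce_dz = w * (p - y) / n

    tp = float(np.sum(p * y))
    fn = float(np.sum((1 - p) * y))
    fp = float(np.sum(p * (1 - y)))
    denom = tp + alpha * fn + beta * fp
    if denom == 0:  # no positives and no positive mass: define TI = 1 (no error)
        ti = 1.0
        dftl_dz = np.zeros_like(z)
        ftl = 0.0
    else:
        ti = tp / denom
        one_minus = max(1.0 - ti, 1e-12)
        ftl = one_minus**gamma
        ddenom_dp = y - alpha * y + beta * (1 - y)
        dti_dp = (y * denom - tp * ddenom_dp) / denom**2
        dftl_dp = -gamma * one_minus ** (gamma - 1) * dti_dp
        dftl_dz = dftl_dp * p * (1 - p)

    loss = loss_mix * bce + (1 - loss_mix) * ftl
    dz = loss_mix * dbce_dz + (1 - loss_mix) * dftl_dz
    return loss, dz
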