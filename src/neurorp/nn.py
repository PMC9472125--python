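"""A small NumPy neural-network engine for the time-distributed CNN-LSTM.

Implements exactly the layers the classifier needs — 2-D convolution
(stride 1, `same` padding, im2col/BLAS), ReLU, 2x2 max-pooling, dense
layers, an LSTM and a softmax/cross-entropy head — with reverse-mode
gradients and an Adam optimizer.  Everything is float32 and deterministic
given the seed used for initialization and shuffling.

Tensor conventions: images are (N, H, W, C); sequences are (N, T, ...).
Every layer caches what its backward pass needs on ``forward`` and
accumulates parameter gradients on ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "LSTM",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

F32 = np.float32


class Layer:
    def params(self):
        """List of (name, value, grad) parameter triples."""
        return []

    def zero_grad(self) -> None:
        for _, _, g in self.params():
            g[...] = 0

    def forward(self, x, train: bool = True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv2D(Layer):
    """3x3-style convolution, stride 1, `same` zero padding, NHWC layout.

    Weights are stored as (C_in, kh, kw, C_out) so the im2col view
    (..., C_in, kh, kw) flattens straight into the GEMM operand.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        self.W = _glorot(rng, (c_in, kernel, kernel, c_out), fan_in, c_out)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, kh, kw) -> (N*H*W, C*kh*kw)
        v = sliding_window_view(xp, (k, k), axis=(1, 2))
        n, h, w = x.shape[0], x.shape[1], x.shape[2]
        return np.ascontiguousarray(v).reshape(n * h * w, -1)

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=F32)
        n, h, w, _ = x.shape
        col = self._im2col(x)
        y = col @ self.W.reshape(-1, self.c_out) + self.b
        if train:
            self._cache = (col, x.shape)
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy):
        col, xshape = self._cache
        n, h, w, _ = xshape
        dy_flat = np.ascontiguousarray(dy, dtype=F32).reshape(n * h * w, self.c_out)
        self.dW += (col.T @ dy_flat).reshape(self.W.shape)
        self.db += dy_flat.sum(axis=0)
        # dx: correlate dy with the spatially flipped, channel-transposed kernel
        k = self.kernel
        p = k // 2
        w_rot = self.W[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (C_out, kh, kw, C_in)
        dyp = np.pad(dy.reshape(n, h, w, self.c_out), ((0, 0), (p, p), (p, p), (0, 0)))
        v = sliding_window_view(dyp, (k, k), axis=(1, 2))  # (N,H,W,C_out,kh,kw)
        dcol = np.ascontiguousarray(v).reshape(n * h * w, -1)
        dx = dcol @ w_rot.reshape(-1, self.c_in)
        del self._cache
        return dx.reshape(n, h, w, self.c_in)


class ReLU(Layer):
    def forward(self, x, train: bool = True):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x, train: bool = True):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        y = xc.max(axis=(2, 4))
        if train:
            # distribute gradient equally over ties to keep backward exact
            mask = xc == y[:, :, None, :, None, :]
            self._cache = (mask, mask.sum(axis=(2, 4), keepdims=True), x.shape)
        return y

    def backward(self, dy):
        mask, ties, xshape = self._cache
        n, h, w, c = xshape
        h2, w2 = h // 2, w // 2
        dxc = mask * (dy[:, :, None, :, None, :] / ties)
        dx = np.zeros(xshape, dtype=F32)
        dx[:, : 2 * h2, : 2 * w2, :] = dxc.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, train: bool = True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (d_in, d_out), d_in, d_out)
        self.b = np.zeros(d_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=F32)
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dy = np.ascontiguousarray(dy, dtype=F32)
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


def _sigmoid(x):
    # evaluated via exp(-|x|) so large magnitudes cannot overflow
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


class LSTM(Layer):
    """Single-layer LSTM over (N, T, D); returns the last hidden state (N, U).

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias is initialized to 1.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx = _glorot(rng, (d_in, 4 * units), d_in, units)
        self.Wh = _glorot(rng, (units, 4 * units), units, units)
        self.b = np.zeros(4 * units, dtype=F32)
        self.b[units : 2 * units] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("Wx", self.Wx, self.dWx), ("Wh", self.Wh, self.dWh), ("b", self.b, self.db)]

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=F32)
        n, t, _ = x.shape
        u = self.units
        h = np.zeros((n, u), dtype=F32)
        c = np.zeros((n, u), dtype=F32)
        steps = []
        for k in range(t):
            z = x[:, k] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            if train:
                steps.append((x[:, k], h, i, f, g, o, c_prev, tc))
        if train:
            self._cache = (steps, x.shape)
        return h

    def backward(self, dy):
        steps, xshape = self._cache
        n, t, d = xshape
        u = self.units
        dx = np.zeros(xshape, dtype=F32)
        dh = np.ascontiguousarray(dy, dtype=F32)
        dc = np.zeros((n, u), dtype=F32)
        for k in range(t - 1, -1, -1):
            xk, h, i, f, g, o, c_prev, tc = steps[k]
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.empty((n, 4 * u), dtype=F32)
            dz[:, :u] = di * i * (1 - i)
            dz[:, u : 2 * u] = df * f * (1 - f)
            dz[:, 2 * u : 3 * u] = dg * (1 - g * g)
            dz[:, 3 * u :] = do * o * (1 - o)
            self.dWx += xk.T @ dz
            h_prev = steps[k - 1][1] if k > 0 else np.zeros((n, u), dtype=F32)
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, k] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        del self._cache
        return dx


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train: bool = True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits.

    ``y`` holds integer class indices.
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), (dlogits / n).astype(F32)


class Adam:
    """Adam with bias correction; one slot pair per registered parameter."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in self.params]
        self.v = [np.zeros_like(v) for _, v, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (_, val, grad), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad * grad
            val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
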