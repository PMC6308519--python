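"""Minimal CPU neural-network layers with explicit backpropagation.

Just enough machinery for the context-encoder model: 3x3 convolutions
(im2col), batch normalisation with Keras-style running-average momentum,
leaky/plain rectifiers, tanh/sigmoid, dropout, nearest-neighbour 2x
upsampling, dense and channel-wise dense layers, and an Adam optimiser.
All tensors are float32 NCHW.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2D", "BatchNorm2D", "LeakyReLU", "ReLU", "Tanh",
    "Dropout", "Upsample2x", "Flatten", "Dense", "ChannelwiseDense",
    "Sequential", "Adam", "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


def _same_pad(size: int, stride: int, k: int) -> tuple[int, int]:
    """'same' padding (more on the far side), output ceil(size/stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


class Conv2D(Layer):
    """3x3 (or kxk) convolution, 'same' padding, stride 1 or 2.

    Implemented as k*k shifted batched matmuls over the channel axis —
    on a single CPU this beats both im2col (large strided copies) and
    direct loops at these small channel counts."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.stride = stride

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, s = self.k, self.stride
        n, c, h, w = x.shape
        ph = _same_pad(h, s, k)
        pw = _same_pad(w, s, k)
        xp = np.pad(x, ((0, 0), (0, 0), ph, pw))
        oh = -(-h // s)
        ow = -(-w // s)
        c_out = self.w.shape[0]
        out = np.zeros((n, c_out, oh * ow), dtype=np.float32)
        slices = []
        for ki in range(k):
            for kj in range(k):
                xs = np.ascontiguousarray(
                    xp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s]
                ).reshape(n, c, oh * ow)
                out += self.w[:, :, ki, kj] @ xs
                slices.append(xs)
        self._cache = (slices, x.shape, xp.shape, ph, pw, oh, ow)
        out += self.b[None, :, None]
        return out.reshape(n, c_out, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        slices, xshape, xpshape, ph, pw, oh, ow = self._cache
        n, c, h, w = xshape
        k, s = self.k, self.stride
        c_out = self.w.shape[0]
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(n, c_out, oh * ow)
        self.db[...] = dyf.sum(axis=(0, 2))
        dxp = np.zeros(xpshape, dtype=np.float32)
        wt = np.ascontiguousarray(self.w.transpose(1, 0, 2, 3))
        dyt = np.ascontiguousarray(dyf.transpose(1, 0, 2)).reshape(c_out, -1)
        for idx, (ki, kj) in enumerate(
            (i, j) for i in range(k) for j in range(k)
        ):
            xs = slices[idx]
            xst = xs.transpose(1, 0, 2).reshape(c, -1)
            self.dw[:, :, ki, kj] = dyt @ xst.T
            dxs = wt[:, :, ki, kj] @ dyf  # (c_in, c_out) @ (n, c_out, p)
            dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dxs.reshape(
                n, c, oh, ow
            )
        return dxp[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class BatchNorm2D(Layer):
    """Per-channel batch normalisation; ``momentum`` weights the running
    statistics (running = m * running + (1 - m) * batch)."""

    def __init__(self, channels: int, momentum: float = 0.8, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        if not train:
            return dy * g
        m = shape[0] * shape[2] * shape[3]
        dxhat = dy * self.gamma[None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv[None, :, None, None]

    def params_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, train):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y * self._y)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Upsample2x(Layer):
    """Nearest-neighbour 2x2 upsampling."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ChannelwiseDense(Layer):
    """Per-channel fully-connected map between spatial layouts.

    Connects encoder features to the decoder seed without mixing channels:
    each of the C channels has its own (out_h*out_w) x (in_h*in_w) weight.
    """

    def __init__(self, channels: int, in_hw: tuple[int, int],
                 out_hw: tuple[int, int], rng: np.random.Generator):
        n_in = in_hw[0] * in_hw[1]
        n_out = out_hw[0] * out_hw[1]
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((channels, n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros((channels, n_out), dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.in_hw = in_hw
        self.out_hw = out_hw

    def forward(self, x, train):
        n, c, h, w = x.shape
        xf = x.reshape(n, c, h * w)
        self._xf = xf
        out = np.einsum("nci,cio->nco", xf, self.w) + self.b
        return out.reshape(n, c, *self.out_hw)

    def backward(self, dy):
        n, c = dy.shape[:2]
        dyf = dy.reshape(n, c, -1)
        self.dw[...] = np.einsum("nci,nco->cio", self._xf, dyf)
        self.db[...] = dyf.sum(axis=0)
        dx = np.einsum("nco,cio->nci", dyf, self.w)
        return dx.reshape(n, c, *self.in_hw)

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out

    def n_params(self) -> int:
        return sum(int(p.size) for p, _ in self.params_grads())

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable + running-statistic arrays, for (de)serialisation."""
        arrays = [p for p, _ in self.params_grads()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2D):
                arrays.extend([layer.run_mean, layer.run_var])
        return arrays


class Adam:
    """Adam optimiser over a fixed parameter/gradient list."""

    def __init__(self, params_grads, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pg = params_grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params_grads]
        self.v = [np.zeros_like(p) for p, _ in params_grads]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
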