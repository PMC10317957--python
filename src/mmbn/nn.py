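"""Small numpy neural-network backend: layers, losses, Adam.

Supports exactly what the attention CNN needs — stride-1 same-padding 2-D
convolution (channels-last), dense layers, ReLU/sigmoid, global average
pooling, channel gating, batch normalization and softmax cross-entropy —
with explicit forward/backward passes in float32. Convolutions avoid im2col
memory blow-up by accumulating one GEMM per kernel tap (9 for a 3x3
kernel), which is also how the backward pass is computed.

Every layer caches what its backward pass needs, so each instance must be
used once per forward graph. All randomness flows through an explicit
``numpy.random.Generator``; given a seed, training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2D",
    "Dense",
    "ReLU",
    "Sigmoid",
    "GlobalAvgPool",
    "ChannelGate",
    "BatchNorm",
    "SoftmaxCrossEntropy",
    "Adam",
    "glorot_uniform",
]

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _tap_regions(k: int, H: int, W: int):
    """Valid slice pairs for each kernel tap of a same-padded conv.

    Yields (dy, dx, out_rows, out_cols, in_rows, in_cols) such that
    out[:, out_rows, out_cols] receives x[:, in_rows, in_cols] under the
    spatial offset (dy - k//2, dx - k//2).
    """
    p = k // 2
    for dy in range(k):
        oy0, oy1 = max(0, p - dy), min(H, H + p - dy)
        iy0, iy1 = oy0 + dy - p, oy1 + dy - p
        for dx in range(k):
            ox0, ox1 = max(0, p - dx), min(W, W + p - dx)
            ix0, ix1 = ox0 + dx - p, ox1 + dx - p
            yield dy, dx, slice(oy0, oy1), slice(ox0, ox1), slice(iy0, iy1), slice(ix0, ix1)


class Conv2D:
    """Stride-1, same-padding 2-D convolution, NHWC layout.

    Kernel size must be odd (1 or 3 in this package); weight shape is
    (kh, kw, c_in, c_out). Each pass runs as one GEMM over all kernel taps
    followed by shifted slice accumulation, which keeps BLAS near peak
    instead of copying an im2col buffer per tap.
    """

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        if ksize % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.ksize = ksize
        fan_in = ksize * ksize * c_in
        self.W = Param(glorot_uniform(rng, (ksize, ksize, c_in, c_out), fan_in, c_out))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, Wd, C = x.shape
        k = self.ksize
        O = self.W.value.shape[-1]
        self._x = x
        # (C, k*k*O): all taps in one GEMM
        Wmat = self.W.value.reshape(k * k, C, O).transpose(1, 0, 2).reshape(C, k * k * O)
        Y = (np.ascontiguousarray(x).reshape(-1, C) @ Wmat).reshape(B, H, Wd, k * k, O)
        out = np.broadcast_to(self.b.value, (B, H, Wd, O)).copy()
        for dy, dx, oy, ox, iy, ix in _tap_regions(k, H, Wd):
            out[:, oy, ox, :] += Y[:, iy, ix, dy * k + dx, :]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        B, H, Wd, C = x.shape
        k = self.ksize
        O = g.shape[-1]
        gf = np.ascontiguousarray(g).reshape(-1, O)
        self.b.grad += gf.sum(axis=0)
        if k == 1:
            self.W.grad[0, 0] += x.reshape(-1, C).T @ gf
            return (gf @ self.W.value[0, 0].T).reshape(x.shape)

        # Gsh aligns g to input positions per tap: Gsh[:, pos, tap, :] is the
        # upstream gradient whose receptive field covers input pos at that
        # tap. One buffer then serves both weight and input gradients:
        #   dW = x^T Gsh  and  dx = Gsh W  (full correlation as one GEMM).
        Gsh = np.zeros((B, H, Wd, k * k, O), dtype=DTYPE)
        for dy, dx_, oy, ox, iy, ix in _tap_regions(k, H, Wd):
            Gsh[:, iy, ix, dy * k + dx_, :] = g[:, oy, ox, :]
        Gf = Gsh.reshape(-1, k * k * O)
        dWmat = x.reshape(-1, C).T @ Gf
        self.W.grad += dWmat.reshape(C, k * k, O).transpose(1, 0, 2).reshape(k, k, C, O)
        Wrows = self.W.value.reshape(k * k, C, O).transpose(0, 2, 1).reshape(k * k * O, C)
        return (Gf @ Wrows).reshape(x.shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out, dtype=DTYPE))
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        x = self._x
        self._x = None
        return g @ self.W.value.T


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        m = self._mask
        self._mask = None
        return g * m


class Sigmoid:
    params: list = []

    def __init__(self):
        self._out = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = self._out
        self._out = None
        return g * out * (1.0 - out)


class GlobalAvgPool:
    """(B, H, W, C) -> (B, C) channel-wise spatial mean."""

    params: list = []

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        self._shape = None
        return np.broadcast_to(g[:, None, None, :] / (H * W), (B, H, W, C)).astype(DTYPE).copy()


class ChannelGate:
    """Multiply feature maps (B, H, W, C) by per-sample channel gates (B, C)."""

    params: list = []

    def __init__(self):
        self._maps = None
        self._gates = None

    def forward(self, maps: np.ndarray, gates: np.ndarray) -> np.ndarray:
        self._maps = maps
        self._gates = gates
        return maps * gates[:, None, None, :]

    def backward(self, g: np.ndarray):
        dmaps = g * self._gates[:, None, None, :]
        dgates = (g * self._maps).sum(axis=(1, 2))
        self._maps = self._gates = None
        return dmaps, dgates


class BatchNorm:
    """Per-channel batch normalization over (batch, height, width).

    Training mode normalizes by mini-batch statistics (biased variance,
    ``eps`` inside the square root) and updates exponential running
    statistics; inference mode uses the running statistics.
    """

    def __init__(self, n_channels: int, eps: float = 1e-3, momentum: float = 0.9):
        self.gamma = Param(np.ones(n_channels, dtype=DTYPE))
        self.beta = Param(np.zeros(n_channels, dtype=DTYPE))
        self.eps = DTYPE(eps)
        self.momentum = momentum
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv, x.shape[0] * x.shape[1] * x.shape[2])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._cache
        self._cache = None
        axes = (0, 1, 2)
        self.beta.grad += g.sum(axis=axes)
        self.gamma.grad += (g * xhat).sum(axis=axes)
        gx = g * self.gamma.value
        return inv * (gx - gx.mean(axis=axes) - xhat * (gx * xhat).mean(axis=axes))


class SoftmaxCrossEntropy:
    """Fused softmax + mean cross-entropy over a batch of logits."""

    def __init__(self):
        self._probs = None
        self._y = None

    @staticmethod
    def probs(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def forward(self, logits: np.ndarray, y: np.ndarray) -> float:
        p = self.probs(logits)
        self._probs, self._y = p, y
        return float(-np.log(np.maximum(p[np.arange(len(y)), y], 1e-12)).mean())

    def backward(self) -> np.ndarray:
        p, y = self._probs, self._y
        self._probs = self._y = None
        g = p.copy()
        g[np.arange(len(y)), y] -= 1.0
        return g / DTYPE(len(y))


class Adam:
    """Adam optimizer with Keras-style defaults."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= DTYPE(self.lr) * (m / b1t) / (np.sqrt(v / b2t) + DTYPE(self.eps))
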