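"""Minimal 3-D convolutional network stack on NumPy.

The translation and classification networks in this package are small
volumetric CNNs that must run on a plain CPU without a deep-learning
framework, so this module provides exactly the layers they need — stride-1
same-padding 3-D convolution (im2col + BLAS matmul), 2x average pooling and
nearest-neighbour upsampling, instance normalization, pointwise
nonlinearities, residual wrapping, a linear head — together with reverse-mode
backprop and an Adam optimizer.

Layers are stateless with respect to activations: ``forward`` returns
``(y, cache)`` and ``backward(dy, cache)`` returns ``dx`` while accumulating
parameter gradients, so one network object can be applied several times in a
single step (as the cycle loss requires) and differentiated through each
application independently. All analytic gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32
_EPS_PROB = 1e-7


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*k^3) patch matrix, zero-padded."""
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    d, h, w = x.shape[1:]
    return np.ascontiguousarray(
        sw.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, -1)
    )


class Conv3d(Layer):
    """Stride-1, same-padding 3-D convolution with odd kernel size."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None,
                 weight_scale: float | None = None, bias_init: float = 0.0,
                 dtype=DEFAULT_DTYPE):
        assert k % 2 == 1, "kernel size must be odd for same padding"
        rng = rng or np.random.default_rng(0)
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / (cin * k**3))
        self.k, self.pad = k, k // 2
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, k, k, k)).astype(dtype))
        self.b = Param(np.full((cout,), bias_init, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.W.value.dtype)
        d, h, w = x.shape[1:]
        cols = _im2col(x, self.k, self.pad)
        y = cols @ self.W.value.reshape(self.cout, -1).T + self.b.value
        return y.reshape(d, h, w, self.cout).transpose(3, 0, 1, 2), (x.shape, cols)

    def backward(self, dy, cache):
        shape, cols = cache
        d, h, w = shape[1:]
        dyf = np.ascontiguousarray(dy.transpose(1, 2, 3, 0).reshape(-1, self.cout),
                                   dtype=cols.dtype)
        self.W.grad += (dyf.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=0)
        # dx = same-pad conv of dy with the channel-transposed, flipped kernel
        wt = self.W.value.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        dcols = _im2col(np.ascontiguousarray(dy, dtype=cols.dtype), self.k, self.pad)
        dx = dcols @ wt.reshape(self.cin, -1).T
        return dx.reshape(d, h, w, self.cin).transpose(3, 0, 1, 2)


class AvgPool2(Layer):
    """2x2x2 average pooling (requires even spatial dims)."""

    def forward(self, x):
        c, d, h, w = x.shape
        assert d % 2 == h % 2 == w % 2 == 0, "AvgPool2 needs even dims"
        y = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))
        return y, x.shape

    def backward(self, dy, cache):
        c, d, h, w = cache
        dx = np.repeat(np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2), 2, axis=3)
        return dx / 8.0


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        y = np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)
        return y, x.shape

    def backward(self, dy, cache):
        c, d, h, w = cache
        return dy.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6))


class InstanceNorm(Layer):
    """Per-channel normalization over spatial dims with learned affine."""

    def __init__(self, c: int, eps: float = 1e-5, dtype=DEFAULT_DTYPE):
        self.eps = eps
        self.gamma = Param(np.ones((c, 1, 1, 1), dtype=dtype))
        self.beta = Param(np.zeros((c, 1, 1, 1), dtype=dtype))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        ax = (1, 2, 3)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xn = (x - mu) * istd
        return self.gamma.value * xn + self.beta.value, (xn, istd)

    def backward(self, dy, cache):
        xn, istd = cache
        ax = (1, 2, 3)
        n = xn[0].size
        self.gamma.grad += (dy * xn).sum(axis=ax, keepdims=True)
        self.beta.grad += dy.sum(axis=ax, keepdims=True)
        dxn = dy * self.gamma.value
        return (istd / n) * (
            n * dxn - dxn.sum(axis=ax, keepdims=True)
            - xn * (dxn * xn).sum(axis=ax, keepdims=True)
        )


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, cache):
        return np.where(cache, dy, self.slope * dy)


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, dy, cache):
        return dy * cache * (1.0 - cache)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, cache):
        return dy * (1.0 - cache**2)


class GlobalAvgPool(Layer):
    """(C, D, H, W) -> (C,)."""

    def forward(self, x):
        return x.mean(axis=(1, 2, 3)), x.shape

    def backward(self, dy, cache):
        c, d, h, w = cache
        return np.broadcast_to(dy[:, None, None, None], cache) / (d * h * w)


class GlobalAvgMaxPool(Layer):
    """(C, D, H, W) -> (2C,): per-channel mean concatenated with per-channel max.

    The max half gives focal signals (e.g. a small hot ROI) a head that does
    not dilute them by the volume size.
    """

    def forward(self, x):
        c = x.shape[0]
        flat = x.reshape(c, -1)
        idx = flat.argmax(axis=1)
        y = np.concatenate([flat.mean(axis=1), flat[np.arange(c), idx]])
        return y, (x.shape, idx)

    def backward(self, dy, cache):
        shape, idx = cache
        c = shape[0]
        n = shape[1] * shape[2] * shape[3]
        dx = np.broadcast_to(dy[:c, None], (c, n)) / n
        dx = np.ascontiguousarray(dx)
        dx[np.arange(c), idx] += dy[c:]
        return dx.reshape(shape)


class Linear(Layer):
    def __init__(self, fin: int, fout: int, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0, np.sqrt(2.0 / fin), size=(fout, fin)).astype(dtype))
        self.b = Param(np.zeros((fout,), dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        return self.W.value @ x + self.b.value, x

    def backward(self, dy, cache):
        self.W.grad += np.outer(dy, cache)
        self.b.grad += dy
        return self.W.value.T @ dy


class LogSoftmax(Layer):
    def forward(self, x):
        y = x - (x.max() + np.log(np.exp(x - x.max()).sum()))
        return y, y

    def backward(self, dy, cache):
        return dy - np.exp(cache) * dy.sum()


class Residual(Layer):
    """y = x + inner(x); inner must preserve shape."""

    def __init__(self, inner: "Sequential"):
        self.inner = inner

    def params(self):
        return self.inner.params()

    def forward(self, x):
        y, caches = self.inner.forward(x)
        return x + y, caches

    def backward(self, dy, cache):
        return dy + self.inner.backward(dy, cache)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(arrays):
            raise ValueError("state length mismatch")
        for p, a in zip(own, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value[...] = a


class Adam:
    """Adam with a mutable learning rate (for plateau schedules)."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# Loss kernels (shared by the GAN and the evaluation battery)
# ---------------------------------------------------------------------------

def bce(probs: np.ndarray, target: float) -> float:
    """Mean binary cross-entropy of probabilities against a constant label.

    Probabilities must lie in (0, 1); they are clipped a hair inside the open
    interval for numerical safety only.
    """
    p = np.asarray(probs, dtype=np.float64)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("BCE scores must lie in (0, 1)")
    p = np.clip(p, _EPS_PROB, 1.0 - _EPS_PROB)
    return float(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean())


def bce_grad(probs: np.ndarray, target: float) -> np.ndarray:
    """d(mean BCE)/d probs."""
    p = np.clip(np.asarray(probs, dtype=np.float64), _EPS_PROB, 1.0 - _EPS_PROB)
    return ((-target / p + (1.0 - target) / (1.0 - p)) / p.size).astype(probs.dtype)


def l1(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute voxel difference."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.abs(np.asarray(a, dtype=np.float64) - b).mean())


def l1_grad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """d(mean |a - b|)/d a (sign convention: 0 at exact ties)."""
    return (np.sign(a - b) / a.size).astype(a.dtype)


def nll(log_probs: np.ndarray, label: int) -> float:
    """Negative log likelihood of the true class."""
    return float(-log_probs[label])


def nll_grad(log_probs: np.ndarray, label: int) -> np.ndarray:
    g = np.zeros_like(log_probs)
    g[label] = -1.0
    return g
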