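"""Minimal NumPy neural-network layers with explicit backpropagation.

The network this package trains is small (a few hundred thousand
parameters), so a BLAS-backed implementation is fast enough for CPU
training at the problem sizes the package targets. All spatial layers
operate on ``float32`` arrays in channel-last (NHWC) layout; convolution
is computed as k*k shifted GEMMs, which keeps memory traffic low
compared with materializing im2col column matrices.

Conventions
-----------
* ``forward(x, train=...)`` caches whatever the backward pass needs only
  when ``train=True``.
* ``backward(dy)`` accumulates parameter gradients into the layer's grad
  arrays (so one batch may be processed in several micro-batches) and
  returns ``dx``.
* Parameters and gradients are exposed as ``{name: array}`` dicts and
  updated in place by the optimizer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_F32 = np.float32

# direct JIT kernels beat BLAS-via-temporaries when the channel product is
# small (the early layers, which dominate memory traffic)
_DIRECT_CONV_MAX_CHANNELS = 48


@njit(cache=True)
def _direct_conv3_fwd(xp, w, b, out):  # pragma: no cover - jitted
    # planar layout: xp (n, cin, h+2, w+2), out (n, cout, h, w); the
    # unit-stride inner loop over image columns SIMD-vectorizes
    n, cin, hp, wp = xp.shape
    cout = w.shape[2]
    h, wd = hp - 2, wp - 2
    for ni in range(n):
        for o in range(cout):
            for i in range(h):
                row = out[ni, o, i]
                for j in range(wd):
                    row[j] = b[o]
                for c in range(cin):
                    for a in range(3):
                        for bb in range(3):
                            wv = w[a * 3 + bb, c, o]
                            src = xp[ni, c, i + a]
                            for j in range(wd):
                                row[j] += wv * src[j + bb]


@njit(cache=True)
def _bn_stats(x2, out_mean, out_var):  # pragma: no cover - jitted
    m, c = x2.shape
    s = np.zeros(c, np.float64)
    ss = np.zeros(c, np.float64)
    for i in range(m):
        for j in range(c):
            v = x2[i, j]
            s[j] += v
            ss[j] += v * v
    for j in range(c):
        mean = s[j] / m
        out_mean[j] = mean
        out_var[j] = ss[j] / m - mean * mean


@njit(cache=True)
def _bn_fwd(x2, mean, inv_std, gamma, beta, xh2, y2):  # pragma: no cover - jitted
    m, c = x2.shape
    for i in range(m):
        for j in range(c):
            v = (x2[i, j] - mean[j]) * inv_std[j]
            xh2[i, j] = v
            y2[i, j] = gamma[j] * v + beta[j]


@njit(cache=True)
def _bn_bwd(dy2, xh2, gamma, inv_std, dgamma, dbeta, dx2):  # pragma: no cover
    m, c = dy2.shape
    s1 = np.zeros(c, np.float64)
    s2 = np.zeros(c, np.float64)
    for i in range(m):
        for j in range(c):
            d = dy2[i, j]
            s1[j] += d * xh2[i, j]
            s2[j] += d
    for j in range(c):
        dgamma[j] += s1[j]
        dbeta[j] += s2[j]
    for i in range(m):
        for j in range(c):
            dx2[i, j] = inv_std[j] * gamma[j] * (
                dy2[i, j] - s2[j] / m - xh2[i, j] * s1[j] / m
            )


@njit(cache=True)
def _maxpool_fwd(x, p, out, idx):  # pragma: no cover - jitted
    n, h, w, c = x.shape
    for ni in range(n):
        for i in range(h // p):
            for j in range(w // p):
                for ch in range(c):
                    best = x[ni, i * p, j * p, ch]
                    bi = 0
                    for a in range(p):
                        for b in range(p):
                            v = x[ni, i * p + a, j * p + b, ch]
                            if v > best:  # strict: first maximum wins ties
                                best = v
                                bi = a * p + b
                    out[ni, i, j, ch] = best
                    idx[ni, i, j, ch] = bi


@njit(cache=True)
def _maxpool_bwd(dy, idx, p, dx):  # pragma: no cover - jitted
    n, ho, wo, c = dy.shape
    for ni in range(n):
        for i in range(ho):
            for j in range(wo):
                for ch in range(c):
                    b = idx[ni, i, j, ch]
                    dx[ni, i * p + b // p, j * p + b % p, ch] += dy[ni, i, j, ch]


@njit(cache=True)
def _direct_conv3_dw(xp, dy, dw, db):  # pragma: no cover - jitted
    # planar layout: xp (n, cin, h+2, w+2), dy (n, cout, h, w)
    n, cin, hp, wp = xp.shape
    cout = dy.shape[1]
    h, wd = hp - 2, wp - 2
    acc = np.zeros((9, cin, cout), np.float64)
    bacc = np.zeros(cout, np.float64)
    for ni in range(n):
        for o in range(cout):
            for i in range(h):
                drow = dy[ni, o, i]
                s = 0.0
                for j in range(wd):
                    s += drow[j]
                bacc[o] += s
                for c in range(cin):
                    for a in range(3):
                        for bb in range(3):
                            src = xp[ni, c, i + a]
                            t = 0.0
                            for j in range(wd):
                                t += drow[j] * src[j + bb]
                            acc[a * 3 + bb, c, o] += t
    dw += acc.astype(np.float32)
    db += bacc.astype(np.float32)


class Layer:
    """Base class: a differentiable operation with optional parameters."""

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


def _shifted_gemm_conv(x: np.ndarray, w: np.ndarray, b) -> np.ndarray:
    """'Same'-padded stride-1 convolution of NHWC ``x`` with ``w`` (k*k, Cin, Cout)."""
    n, h, wd, cin = x.shape
    k = int(np.sqrt(w.shape[0]))
    cout = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros((n * h * wd, cout), _F32)
    for a in range(k):
        for c in range(k):
            seg = xp[:, a : a + h, c : c + wd, :].reshape(-1, cin)
            out += seg @ w[a * k + c]
    if b is not None:
        out += b
    return out.reshape(n, h, wd, cout)


class Conv2d(Layer):
    """k x k convolution, stride 1, size-preserving (zero) padding, NHWC.

    ``first=True`` marks the extractor's input layer, whose input gradient
    is never needed and therefore skipped.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 first: bool = False):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for size-preserving padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.first = first
        fan_in = c_in * kernel * kernel
        # He initialization, appropriate for the ReLU nonlinearity that follows
        self.w = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (kernel * kernel, c_in, c_out)
        ).astype(_F32)
        self.b = np.zeros(c_out, _F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None
        self._xp = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def _use_direct(self) -> bool:
        return (
            self.kernel == 3 and self.c_in * self.c_out <= _DIRECT_CONV_MAX_CHANNELS
        )

    @staticmethod
    def _to_planar_padded(x):
        """NHWC -> contiguous NCHW with 1-px zero padding."""
        return np.pad(
            np.ascontiguousarray(x.transpose(0, 3, 1, 2)),
            ((0, 0), (0, 0), (1, 1), (1, 1)),
        )

    def forward(self, x, train=False, rng=None):
        if self._use_direct():
            n, h, wd, _ = x.shape
            xp = self._to_planar_padded(x)
            if train:
                self._xp = xp  # reused by backward, saves a transpose+pad
            out = np.empty((n, self.c_out, h, wd), _F32)
            _direct_conv3_fwd(xp, self.w, self.b, out)
            return np.ascontiguousarray(out.transpose(0, 2, 3, 1))
        if train:
            self._x = x
        return _shifted_gemm_conv(x, self.w, self.b)

    def backward(self, dy):
        k = self.kernel
        dy = np.ascontiguousarray(dy)
        if self._use_direct():
            dyp = np.ascontiguousarray(dy.transpose(0, 3, 1, 2))
            _direct_conv3_dw(self._xp, dyp, self.dw, self.db)
            self._xp = None
        else:
            x = self._x
            n, h, wd, _ = x.shape
            p = k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            dy2d = dy.reshape(-1, self.c_out)
            for a in range(k):
                for c in range(k):
                    seg = xp[:, a : a + h, c : c + wd, :].reshape(-1, self.c_in)
                    self.dw[a * k + c] += seg.T @ dy2d
            self.db += dy2d.sum(0)
        self._x = None
        if self.first:
            return None  # input gradient unused at the extractor entry
        # dx: correlate dy with the spatially flipped, channel-transposed kernels
        wt = np.ascontiguousarray(self.w[::-1].transpose(0, 2, 1))
        return _shifted_gemm_conv(dy, wt, None)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, _F32(0.0))
        return np.maximum(x, 0.0)

    def backward(self, dy):
        out = dy * self._mask
        self._mask = None
        return out


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    Training forwards normalize by the batch's own statistics and
    additionally pool per-channel sums across batches; calling
    :meth:`adopt_pooled_stats` (the trainer does this once per epoch)
    turns the pooled sums into the inference-mode statistics. Pooling the
    whole epoch avoids the small-batch pitfall where an exponential
    average of per-batch variances underestimates the total variance by
    the between-batch spread of the means, which badly miscalibrates
    inference-mode outputs after short trainings.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = np.ones(c, _F32)
        self.beta = np.zeros(c, _F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, _F32)
        self.running_var = np.ones(c, _F32)
        self.eps = eps
        self._cache = None
        self._acc_n = 0.0
        self._acc_sum = np.zeros(c, np.float64)
        self._acc_sumsq = np.zeros(c, np.float64)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def adopt_pooled_stats(self) -> None:
        """Set inference statistics from the pooled sums, then reset them."""
        if self._acc_n > 0:
            mean = self._acc_sum / self._acc_n
            var = self._acc_sumsq / self._acc_n - mean * mean
            self.running_mean[...] = mean.astype(_F32)
            self.running_var[...] = np.maximum(var, 0.0).astype(_F32)
        self._acc_n = 0.0
        self._acc_sum[...] = 0.0
        self._acc_sumsq[...] = 0.0

    def forward(self, x, train=False, rng=None):
        c = x.shape[-1]
        x2 = np.ascontiguousarray(x).reshape(-1, c)
        if train:
            mean = np.empty(c, _F32)
            var = np.empty(c, _F32)
            _bn_stats(x2, mean, var)
            m = x2.shape[0]
            self._acc_n += m
            self._acc_sum += m * mean.astype(np.float64)
            self._acc_sumsq += m * (var + mean.astype(np.float64) ** 2)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var.astype(np.float64) + self.eps)).astype(_F32)
        xh2 = np.empty_like(x2)
        y2 = np.empty_like(x2)
        _bn_fwd(x2, mean, inv_std, self.gamma, self.beta, xh2, y2)
        if train:
            self._cache = (xh2, inv_std)
        return y2.reshape(x.shape)

    def backward(self, dy):
        xh2, inv_std = self._cache
        self._cache = None
        c = dy.shape[-1]
        dy2 = np.ascontiguousarray(dy).reshape(-1, c)
        dx2 = np.empty_like(dy2)
        _bn_bwd(dy2, xh2, self.gamma, inv_std, self.dgamma, self.dbeta, dx2)
        return dx2.reshape(dy.shape)


class MaxPool2d(Layer):
    """Non-overlapping max pooling with a square window (NHWC)."""

    def __init__(self, window: int = 2):
        self.window = window
        self._idx = None
        self._shape = None

    def forward(self, x, train=False, rng=None):
        p = self.window
        n, h, w, c = x.shape
        if h % p or w % p:
            raise ValueError(f"spatial size ({h},{w}) not divisible by pool {p}")
        x = np.ascontiguousarray(x)
        out = np.empty((n, h // p, w // p, c), _F32)
        idx = np.empty((n, h // p, w // p, c), np.int8)
        _maxpool_fwd(x, p, out, idx)
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, dy):
        p = self.window
        dx = np.zeros(self._shape, _F32)
        _maxpool_bwd(np.ascontiguousarray(dy), self._idx, p, dx)
        self._idx = None
        return dx


class GlobalAvgPool(Layer):
    """(N,H,W,C) -> (N,C) mean over the spatial dimensions."""

    def __init__(self):
        self._hw = None

    def forward(self, x, train=False, rng=None):
        if train:
            self._hw = x.shape[1:3]
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        h, w = self._hw
        n, c = dy.shape
        return np.broadcast_to(
            dy[:, None, None, :] / (h * w), (n, h, w, c)
        ).astype(_F32)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(_F32)
        self.b = np.zeros(d_out, _F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw += self._x.T @ dy
        self.db += dy.sum(0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(_F32) / _F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def param_items(self):
        """Yield (param_array, grad_array) pairs in a stable order."""
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.param_items()
            else:
                p, g = layer.params(), layer.grads()
                for name in p:
                    yield p[name], g[name]


class Adam:
    """Adam with bias correction; updates parameter arrays in place."""

    def __init__(self, param_items, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.items = list(param_items)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.items]
        self.v = [np.zeros_like(p) for p, _ in self.items]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.items, self.m, self.v):
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


# ---------------------------------------------------------------------------
# numerically stable losses on logits (used by the training loop)

def sigmoid(z):
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, y):
    """Mean binary cross-entropy of sigmoid(z) against y; returns (loss, dz)."""
    z = np.asarray(z, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / z.size
    return float(loss), dz.astype(_F32)


def softmax(z):
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def ce_with_logits(z, y_onehot):
    """Mean categorical cross-entropy on logits; returns (loss, dz)."""
    p = softmax(z)
    n = z.shape[0]
    loss = -np.mean(np.sum(y_onehot * np.log(np.clip(p, 1e-12, None)), axis=1))
    dz = (p - y_onehot) / n
    return float(loss), dz.astype(_F32)
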