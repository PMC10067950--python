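"""Minimal reverse-mode neural-network layers on numpy arrays.

Every layer follows the same contract::

    y, cache = layer.forward(x)      # pure w.r.t. the layer's state
    dx = layer.backward(dy, cache)   # accumulates into layer.grads

Caches are explicit, so one layer object can be applied to several inputs
inside a single step (the twin-stream model applies one shared stream to the
right and the left ear image); gradients from every application accumulate
in ``layer.grads`` until :func:`zero_grads` is called.

Arrays are laid out NCHW.  Convolutions use im2col + BLAS matmul.
Normalization is group normalization — statistics are per sample, never per
batch, which makes inference deterministic and side-swap equivariance of the
bilateral model exact at any batch size.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "GroupNorm",
    "ReLU",
    "Dense",
    "SEBlock",
    "ResidualBlock",
    "Sequential",
    "LSEPool",
    "softmax",
    "iter_parameters",
    "zero_grads",
    "parameter_count",
]


def he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    """He (Kaiming) normal initialization: N(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Layer:
    """Base class: parameterized layers override ``params``/``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def children(self):
        return ()

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - abstract
        raise NotImplementedError


def iter_parameters(layer: Layer):
    """Yield ``(owning_layer, name)`` for every parameter, depth first.

    A layer object reached through several parents (weight sharing) is
    visited once.
    """
    seen: set[int] = set()

    def _walk(l: Layer):
        if id(l) in seen:
            return
        seen.add(id(l))
        for name in l.params:
            yield l, name
        for child in l.children():
            yield from _walk(child)

    yield from _walk(layer)


def zero_grads(layer: Layer) -> None:
    for l, name in iter_parameters(layer):
        l.grads[name].fill(0.0)


def parameter_count(layer: Layer) -> int:
    return sum(l.params[name].size for l, name in iter_parameters(layer))


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k
    )
    return cols, ho, wo


def _col2im(dcols, x_shape, k, stride, pad, ho, wo):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    """2-D convolution, 'same' padding for odd kernels when stride divides
    the input evenly (output spatial size = ceil(input / stride))."""

    def __init__(self, in_ch, out_ch, ksize, stride=1, *, rng, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride = ksize, stride
        self.pad = (ksize - 1) // 2
        fan_in = in_ch * ksize * ksize
        self.params = {
            "W": he_normal(rng, (out_ch, in_ch, ksize, ksize), fan_in, dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        w_mat = self.params["W"].reshape(self.out_ch, -1)
        y = cols @ w_mat.T + self.params["b"]
        n = x.shape[0]
        y = y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        return y, (cols, x.shape, ho, wo)

    def backward(self, dy, cache):
        cols, x_shape, ho, wo = cache
        n = x_shape[0]
        dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.grads["W"] += (dy_mat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += dy_mat.sum(axis=0)
        dcols = dy_mat @ self.params["W"].reshape(self.out_ch, -1)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class GroupNorm(Layer):
    """Group normalization with per-channel affine; statistics per sample."""

    def __init__(self, channels, groups=None, eps=1e-5, *, dtype=np.float32):
        super().__init__()
        if groups is None:
            groups = min(8, channels)
        while channels % groups:
            groups -= 1
        self.c, self.g, self.eps = channels, groups, eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        n, c, h, w = x.shape
        xg = x.reshape(n, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv_std).reshape(n, c, h, w)
        y = self.params["gamma"][None, :, None, None] * xhat
        y += self.params["beta"][None, :, None, None]
        return y, (xhat, inv_std)

    def backward(self, dy, cache):
        xhat, inv_std = cache
        n, c, h, w = dy.shape
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        dxh = (dy * self.params["gamma"][None, :, None, None]).reshape(n, self.g, -1)
        xh = xhat.reshape(n, self.g, -1)
        m1 = dxh.mean(axis=2, keepdims=True)
        m2 = (dxh * xh).mean(axis=2, keepdims=True)
        dx = inv_std * (dxh - m1 - xh * m2)
        return dx.reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache


class Dense(Layer):
    def __init__(self, in_features, out_features, *, rng, dtype=np.float32):
        super().__init__()
        self.params = {
            "W": he_normal(rng, (out_features, in_features), in_features, dtype),
            "b": np.zeros(out_features, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        return x @ self.params["W"].T + self.params["b"], x

    def backward(self, dy, cache):
        self.grads["W"] += dy.T @ cache
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SEBlock(Layer):
    """Squeeze-and-excitation channel recalibration.

    Global average pool -> bottleneck (C -> max(C//r, 1) -> C) -> sigmoid
    gate in (0,1) -> channel-wise rescaling of the input.
    """

    def __init__(self, channels, reduction=8, *, rng, dtype=np.float32):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Dense(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = Dense(hidden, channels, rng=rng, dtype=dtype)

    def children(self):
        return (self.fc1, self.fc2)

    def forward(self, x):
        n, c, h, w = x.shape
        s = x.mean(axis=(2, 3))
        z1, c1 = self.fc1.forward(s)
        a1 = np.maximum(z1, 0.0)
        z2, c2 = self.fc2.forward(a1)
        gate = _sigmoid(z2)
        y = x * gate[:, :, None, None]
        return y, (x, gate, z1 > 0, c1, c2, h * w)

    def backward(self, dy, cache):
        x, gate, relu_mask, c1, c2, hw = cache
        dgate = (dy * x).sum(axis=(2, 3))
        dx = dy * gate[:, :, None, None]
        dz2 = dgate * gate * (1.0 - gate)
        da1 = self.fc2.backward(dz2, c2)
        dz1 = da1 * relu_mask
        ds = self.fc1.backward(dz1, c1)
        dx += (ds / hw)[:, :, None, None]
        return dx


class ResidualBlock(Layer):
    """Pre-activation residual block with an SE module on the residual path.

    norm -> relu -> conv3x3(stride) -> norm -> relu -> conv3x3 -> SE, added
    to an identity shortcut (1x1 projection from the pre-activated input
    when the stride or the channel width changes).
    """

    def __init__(self, in_ch, out_ch, stride, se_reduction=8, *, rng, dtype=np.float32):
        super().__init__()
        self.gn1 = GroupNorm(in_ch, dtype=dtype)
        self.relu1 = ReLU()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, rng=rng, dtype=dtype)
        self.gn2 = GroupNorm(out_ch, dtype=dtype)
        self.relu2 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng=rng, dtype=dtype)
        self.se = SEBlock(out_ch, se_reduction, rng=rng, dtype=dtype)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride, rng=rng, dtype=dtype)
        else:
            self.proj = None

    def children(self):
        layers = [self.gn1, self.relu1, self.conv1, self.gn2, self.relu2, self.conv2, self.se]
        if self.proj is not None:
            layers.append(self.proj)
        return tuple(layers)

    def forward(self, x):
        h0, cg1 = self.gn1.forward(x)
        a0, cr1 = self.relu1.forward(h0)
        if self.proj is not None:
            short, cp = self.proj.forward(a0)
        else:
            short, cp = x, None
        h1, cc1 = self.conv1.forward(a0)
        h2, cg2 = self.gn2.forward(h1)
        a2, cr2 = self.relu2.forward(h2)
        h3, cc2 = self.conv2.forward(a2)
        h4, cse = self.se.forward(h3)
        return h4 + short, (cg1, cr1, cp, cc1, cg2, cr2, cc2, cse)

    def backward(self, dy, cache):
        cg1, cr1, cp, cc1, cg2, cr2, cc2, cse = cache
        dh3 = self.se.backward(dy, cse)
        da2 = self.conv2.backward(dh3, cc2)
        dh2 = self.relu2.backward(da2, cr2)
        dh1 = self.gn2.backward(dh2, cg2)
        da0 = self.conv1.backward(dh1, cc1)
        if self.proj is not None:
            da0 += self.proj.backward(dy, cp)
            dh0 = self.relu1.backward(da0, cr1)
            dx = self.gn1.backward(dh0, cg1)
        else:
            dh0 = self.relu1.backward(da0, cr1)
            dx = self.gn1.backward(dh0, cg1)
            dx += dy
        return dx


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        return tuple(self.layers)

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy, cache):
        for layer, c in zip(reversed(self.layers), reversed(cache)):
            dy = layer.backward(dy, c)
        return dy


class LSEPool(Layer):
    """Log-Sum-Exp spatial pooling, per channel.

    ``lse(x) = (1/r) log( mean_{h,w} exp(r * x) )`` computed with a
    max-shift.  Interpolates between mean pooling (r -> 0) and max pooling
    (r -> inf); the gradient is the spatial softmax of ``r * x``.
    """

    def __init__(self, r: float = 5.0):
        super().__init__()
        if r <= 0:
            raise ValueError("LSE sharpness r must be positive")
        self.r = float(r)

    def forward(self, x):
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite input to LSE pooling")
        n, c, h, w = x.shape
        flat = x.reshape(n, c, -1)
        m = flat.max(axis=2, keepdims=True)
        e = np.exp(self.r * (flat - m))
        s = e.sum(axis=2, keepdims=True)
        y = (m + np.log(s / (h * w)) / self.r)[:, :, 0]
        return y, (e / s, (n, c, h, w))

    def backward(self, dy, cache):
        weights, shape = cache
        return (dy[:, :, None] * weights).reshape(shape)


def lse_pool(grid: np.ndarray, r: float) -> float:
    """LSE-pool a single 2-D grid to a scalar (functional convenience)."""
    g = np.asarray(grid, dtype=float)
    if g.ndim != 2:
        raise ValueError("lse_pool expects a 2-D grid")
    y, _ = LSEPool(r).forward(g[None, None])
    return float(y[0, 0])


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
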