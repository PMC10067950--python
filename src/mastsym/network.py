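"""Bilateral symmetry network and the single-side baseline.

The bilateral model processes the two ear images of one subject with a
*single* shared-weight CNN stream.  Each stream application yields a spatial
category-evidence map with one channel per mastoiditis category (normal,
mild, severe); with the default 384x256 input and a 32-fold spatial
reduction the map is 12x8x3.  Each side's mastoiditis classifier applies
Log-Sum-Exp pooling per channel followed by a softmax.

The auxiliary symmetry path takes the element-wise absolute difference of
the two category maps (the symmetry evaluation layer), optionally applies a
learnable 1x1 channel map from category-difference channels to grade
channels, LSE-pools per channel and applies a softmax over the three
symmetry grades.

Because the two streams are one parameter set and the absolute difference
is symmetric, swapping the two input images swaps the two per-side outputs
exactly and leaves the symmetry output unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import prod

import numpy as np

from .nn import (
    Conv2d,
    GroupNorm,
    LSEPool,
    Layer,
    ReLU,
    ResidualBlock,
    Sequential,
    iter_parameters,
    parameter_count,
    softmax,
    zero_grads,
)

__all__ = [
    "StreamConfig",
    "BilateralPrediction",
    "build_stream",
    "symmetry_eval",
    "mastoiditis_head",
    "BilateralSymmetryNet",
    "SingleSideNet",
    "forward_bilateral",
]

N_CATEGORIES = 3
N_GRADES = 3


@dataclass(frozen=True)
class StreamConfig:
    """Architecture of one CNN stream.

    The printed contract is six SE-residual blocks reducing a 384x256 input
    to a 12x8 map with 3 category channels; stride placement, widths, the
    SE reduction ratio and the LSE sharpness are configuration.
    """

    n_blocks: int = 6
    block_strides: tuple[int, ...] = (1, 2, 2, 2, 2, 2)
    block_widths: tuple[int, ...] = (16, 32, 64, 128, 256, 256)
    se_reduction: int = 8
    lse_r: float = 5.0
    input_shape: tuple[int, int] = (384, 256)
    symmetry_head: str = "linear"  # 'linear' | 'direct'

    def __post_init__(self) -> None:
        if len(self.block_strides) != self.n_blocks or len(self.block_widths) != self.n_blocks:
            raise ValueError("block_strides and block_widths must have n_blocks entries")
        if self.lse_r <= 0:
            raise ValueError("lse_r must be positive")
        if self.symmetry_head not in ("linear", "direct"):
            raise ValueError("symmetry_head must be 'linear' or 'direct'")
        red = prod(self.block_strides)
        h, w = self.input_shape
        if h % red or w % red:
            raise ValueError(
                f"input shape {self.input_shape} is not divisible by the total "
                f"stride {red}; the stream cannot produce an integer feature map"
            )

    @property
    def feature_shape(self) -> tuple[int, int, int]:
        """(height, width, channels) of the category feature map."""
        red = prod(self.block_strides)
        return (self.input_shape[0] // red, self.input_shape[1] // red, N_CATEGORIES)

    @classmethod
    def benchmark(cls) -> "StreamConfig":
        """Narrow stream for the 4x-downscaled phantom benchmark (96x64
        inputs -> 3x2x3 maps); widths chosen for CPU-scale training."""
        return cls(
            block_strides=(1, 2, 2, 2, 2, 2),
            block_widths=(4, 8, 16, 16, 24, 24),
            se_reduction=4,
            input_shape=(96, 64),
        )


@dataclass(frozen=True)
class BilateralPrediction:
    """Per-subject outputs: category probabilities per side and the
    symmetry-grade probabilities."""

    right_probs: np.ndarray
    left_probs: np.ndarray
    symmetry_probs: np.ndarray

    def __post_init__(self) -> None:
        for name in ("right_probs", "left_probs", "symmetry_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (3,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a non-negative 3-vector summing to 1")


class Stream(Sequential):
    """One CNN stream: six SE-residual blocks, a final norm/ReLU, and a 1x1
    projection to the category channels."""

    def __init__(self, cfg: StreamConfig, rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        layers: list[Layer] = []
        in_ch = 1
        for width, stride in zip(cfg.block_widths, cfg.block_strides):
            layers.append(
                ResidualBlock(in_ch, width, stride, cfg.se_reduction, rng=rng, dtype=dtype)
            )
            in_ch = width
        layers += [
            GroupNorm(in_ch, dtype=dtype),
            ReLU(),
            Conv2d(in_ch, N_CATEGORIES, 1, rng=rng, dtype=dtype),
        ]
        super().__init__(*layers)

    @property
    def blocks(self) -> list[ResidualBlock]:
        return [l for l in self.layers if isinstance(l, ResidualBlock)]


def build_stream(cfg: StreamConfig, seed: int = 0, dtype=np.float32) -> Stream:
    """Build one He-initialized CNN stream from its configuration."""
    rng = np.random.default_rng(seed)
    return Stream(cfg, rng, dtype=dtype)


def symmetry_eval(right_fm: np.ndarray, left_fm: np.ndarray) -> np.ndarray:
    """Symmetry evaluation layer: element-wise absolute difference of the
    two category feature maps, per channel and pixel.  Symmetric in its
    arguments; every entry is non-negative."""
    r = np.asarray(right_fm)
    l = np.asarray(left_fm)
    if r.shape != l.shape:
        raise ValueError(f"feature map shapes differ: {r.shape} vs {l.shape}")
    return np.abs(r - l)


def mastoiditis_head(fm: np.ndarray, r: float) -> np.ndarray:
    """Classify one category feature map: per-channel LSE pooling then
    softmax.  ``fm`` is (channels, height, width)."""
    fm = np.asarray(fm, dtype=float)
    if fm.ndim != 3:
        raise ValueError("feature map must be (channels, height, width)")
    pooled, _ = LSEPool(r).forward(fm[None])
    return softmax(pooled[0])


def _check_input(x: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != shape:
        raise ValueError(f"expected input images of shape {shape}, got {x.shape}")
    return x


class SingleSideNet(Layer):
    """Baseline: one stream and one mastoiditis classifier, no symmetry
    path."""

    def __init__(self, cfg: StreamConfig | None = None, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.cfg = cfg or StreamConfig()
        rng = np.random.default_rng(seed)
        self.stream = Stream(self.cfg, rng, dtype=dtype)
        self.pool = LSEPool(self.cfg.lse_r)

    def children(self):
        return (self.stream, self.pool)

    def forward(self, x):
        x = _check_input(x, self.cfg.input_shape)
        fm, c_stream = self.stream.forward(x)
        logits, c_pool = self.pool.forward(fm)
        return logits, (c_stream, c_pool)

    def backward(self, dlogits, cache):
        c_stream, c_pool = cache
        dfm = self.pool.backward(dlogits, c_pool)
        return self.stream.backward(dfm, c_stream)

    def predict_proba(self, x) -> np.ndarray:
        """Category probabilities, shape (n, 3)."""
        logits, _ = self.forward(x)
        return softmax(logits, axis=1)


@dataclass
class BilateralOutputs:
    """Batched forward results of the bilateral net, with caches retained
    for the backward pass and feature maps retained for activation maps."""

    right_logits: np.ndarray
    left_logits: np.ndarray
    sym_logits: np.ndarray
    fm_right: np.ndarray
    fm_left: np.ndarray
    diff: np.ndarray
    grade_fm: np.ndarray
    caches: tuple = field(repr=False, default=())

    @property
    def right_probs(self):
        return softmax(self.right_logits, axis=1)

    @property
    def left_probs(self):
        return softmax(self.left_logits, axis=1)

    @property
    def symmetry_probs(self):
        return softmax(self.sym_logits, axis=1)


class BilateralSymmetryNet(Layer):
    """Twin shared-weight streams with the symmetry auxiliary path.

    One ``Stream`` object is applied to both sides, so the two CNNs are the
    same parameter set by construction.  The symmetry head is either
    ``linear`` (learnable 1x1 map from the 3 category-difference channels to
    the 3 grade channels before pooling, the default) or ``direct`` (pool
    the raw difference channels).
    """

    def __init__(self, cfg: StreamConfig | None = None, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.cfg = cfg or StreamConfig()
        rng = np.random.default_rng(seed)
        self.stream = Stream(self.cfg, rng, dtype=dtype)
        self.pool = LSEPool(self.cfg.lse_r)
        if self.cfg.symmetry_head == "linear":
            self.grade_map: Conv2d | None = Conv2d(
                N_CATEGORIES, N_GRADES, 1, rng=rng, dtype=dtype
            )
        else:
            self.grade_map = None

    def children(self):
        layers = [self.stream, self.pool]
        if self.grade_map is not None:
            layers.append(self.grade_map)
        return tuple(layers)

    # -- forward / backward -------------------------------------------------

    def forward(self, inputs):
        """``inputs`` is ``(right, left)``, each (n, 1, H, W) (2-D and 3-D
        arrays are promoted)."""
        xr, xl = inputs
        xr = _check_input(xr, self.cfg.input_shape)
        xl = _check_input(xl, self.cfg.input_shape)
        if xr.shape != xl.shape:
            raise ValueError("right and left batches must have the same shape")
        fm_r, c_r = self.stream.forward(xr)
        fm_l, c_l = self.stream.forward(xl)
        logits_r, cp_r = self.pool.forward(fm_r)
        logits_l, cp_l = self.pool.forward(fm_l)
        diff = symmetry_eval(fm_r, fm_l)
        if self.grade_map is not None:
            grade_fm, c_g = self.grade_map.forward(diff)
        else:
            grade_fm, c_g = diff, None
        logits_s, cp_s = self.pool.forward(grade_fm)
        outs = BilateralOutputs(
            right_logits=logits_r,
            left_logits=logits_l,
            sym_logits=logits_s,
            fm_right=fm_r,
            fm_left=fm_l,
            diff=diff,
            grade_fm=grade_fm,
            caches=(c_r, c_l, cp_r, cp_l, c_g, cp_s),
        )
        return outs, outs.caches

    def backward_outputs(self, outs: BilateralOutputs, d_right, d_left, d_sym) -> None:
        """Accumulate parameter gradients from logit-space upstream
        gradients of the three heads."""
        c_r, c_l, cp_r, cp_l, c_g, cp_s = outs.caches
        dgrade = self.pool.backward(d_sym, cp_s)
        if self.grade_map is not None:
            ddiff = self.grade_map.backward(dgrade, c_g)
        else:
            ddiff = dgrade
        sign = np.sign(outs.fm_right - outs.fm_left)
        dfm_r = self.pool.backward(d_right, cp_r) + ddiff * sign
        dfm_l = self.pool.backward(d_left, cp_l) - ddiff * sign
        self.stream.backward(dfm_r, c_r)
        self.stream.backward(dfm_l, c_l)

    # -- inference ----------------------------------------------------------

    def predict_batch(self, right, left) -> BilateralOutputs:
        outs, _ = self.forward((right, left))
        return outs

    def predict_pair(self, right_image, left_image) -> BilateralPrediction:
        outs = self.predict_batch(right_image, left_image)
        return BilateralPrediction(
            right_probs=outs.right_probs[0],
            left_probs=outs.left_probs[0],
            symmetry_probs=outs.symmetry_probs[0],
        )


def forward_bilateral(net: BilateralSymmetryNet, pair) -> BilateralPrediction:
    """Run one preprocessed paired input through the bilateral model."""
    return net.predict_pair(pair.right_image, pair.left_image)


# -- serialization ----------------------------------------------------------


def architecture_summary(net: Layer) -> dict:
    """JSON-able architecture dump for conformance checks and checkpoints."""
    cfg = asdict(net.cfg)
    blocks = [
        {
            "in_ch": b.conv1.in_ch,
            "out_ch": b.conv1.out_ch,
            "stride": b.conv1.stride,
            "projection": b.proj is not None,
        }
        for b in net.stream.blocks
    ]
    return {
        "class": type(net).__name__,
        "config": cfg,
        "blocks": blocks,
        "n_parameters": parameter_count(net),
        "stream_parameters": parameter_count(net.stream),
    }


def save_weights(net: Layer, path) -> None:
    arrays = {}
    for i, (layer, name) in enumerate(iter_parameters(net)):
        arrays[f"p{i:04d}_{name}"] = layer.params[name]
    arrays["__summary__"] = np.frombuffer(
        json.dumps(architecture_summary(net)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_weights(net: Layer, path) -> None:
    with np.load(path) as data:
        for i, (layer, name) in enumerate(iter_parameters(net)):
            layer.params[name][...] = data[f"p{i:04d}_{name}"]
    zero_grads(net)


def load_model(path):
    """Rebuild a bilateral or single-side model from a checkpoint written
    by :func:`save_weights` (architecture summary travels with the
    weights)."""
    with np.load(path) as data:
        summary = json.loads(bytes(data["__summary__"]))
    cfg_dict = dict(summary["config"])
    for key in ("block_strides", "block_widths", "input_shape"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = StreamConfig(**cfg_dict)
    cls = {"BilateralSymmetryNet": BilateralSymmetryNet, "SingleSideNet": SingleSideNet}[
        summary["class"]
    ]
    net = cls(cfg)
    load_weights(net, path)
    return net
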