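"""Numerics of the layer stack: pooling oracle, SE arithmetic, reverse-mode
gradients against finite differences, optimizer updates."""

import numpy as np
import pytest

from mastsym.nn import (
    Conv2d,
    Dense,
    GroupNorm,
    LSEPool,
    RMSprop,
    SEBlock,
    iter_parameters,
    lse_pool,
    softmax,
    zero_grads,
)
from mastsym.network import BilateralSymmetryNet
from mastsym.training import _ce_and_grad


# -- LSE pooling ------------------------------------------------------------


def test_lse_constant_grid():
    for r in (0.5, 1.0, 5.0, 20.0):
        assert lse_pool(np.full((12, 8), 3.25), r) == pytest.approx(3.25, abs=1e-9)


def test_lse_hand_computed():
    # 2x2 grid (0,0,0,1), r=1: (1/1) log((3 + e)/4)
    grid = np.array([[0.0, 0.0], [0.0, 1.0]])
    assert lse_pool(grid, 1.0) == pytest.approx(np.log((3 + np.e) / 4), abs=1e-12)
    assert lse_pool(grid, 1.0) == pytest.approx(0.35739, abs=5e-5)


def test_lse_bounds_and_max_limit(rng):
    for _ in range(50):
        g = rng.normal(size=(12, 8)) * 3
        for r in (0.5, 2.0, 5.0):
            v = lse_pool(g, r)
            assert g.mean() - 1e-12 <= v <= g.max() + 1e-12
        # r -> inf converges to the max at rate ~ log(HW)/r
        assert abs(lse_pool(g, 200.0) - g.max()) < np.log(96) / 200 + 1e-9


def test_lse_rejects_bad_inputs():
    with pytest.raises(ValueError):
        LSEPool(0.0)
    with pytest.raises(FloatingPointError):
        LSEPool(1.0).forward(np.array([[[np.inf]]])[None])


def test_lse_gradient_is_spatial_softmax(rng):
    pool = LSEPool(3.0)
    x = rng.normal(size=(1, 1, 4, 4))
    _, cache = pool.forward(x)
    dx = pool.backward(np.ones((1, 1)), cache)
    w = np.exp(3.0 * x) / np.exp(3.0 * x).sum()
    np.testing.assert_allclose(dx, w, rtol=1e-10)


# -- squeeze-and-excitation -------------------------------------------------


def test_se_gate_bounds(rng):
    se = SEBlock(4, reduction=2, rng=rng, dtype=np.float64)
    x = rng.normal(size=(2, 4, 5, 5))
    y, _ = se.forward(x)
    assert np.all(np.abs(y) <= np.abs(x) + 1e-12)  # sigmoid gate in (0,1)
    y0, _ = se.forward(np.zeros((1, 4, 3, 3)))
    assert np.all(y0 == 0)


def test_se_hand_computed():
    """1x1 spatial, 2 channels, hand-set weights: evaluate the bottleneck
    arithmetic explicitly."""
    rng = np.random.default_rng(0)
    se = SEBlock(2, reduction=2, rng=rng, dtype=np.float64)
    se.fc1.params["W"][...] = np.array([[1.0, -1.0]])   # 2 -> 1
    se.fc1.params["b"][...] = np.array([0.5])
    se.fc2.params["W"][...] = np.array([[2.0], [-1.0]])  # 1 -> 2
    se.fc2.params["b"][...] = np.array([0.0, 1.0])
    x = np.array([3.0, 1.0]).reshape(1, 2, 1, 1)
    # squeeze s = (3, 1); h = relu(1*3 - 1*1 + 0.5) = 2.5
    # z = (2*2.5 + 0, -1*2.5 + 1) = (5, -1.5); gate = sigmoid(z)
    gate = 1 / (1 + np.exp(-np.array([5.0, -1.5])))
    y, _ = se.forward(x)
    np.testing.assert_allclose(y.ravel(), np.array([3.0, 1.0]) * gate, rtol=1e-12)


# -- normalization ----------------------------------------------------------


def test_groupnorm_standardizes(rng):
    gn = GroupNorm(8, dtype=np.float64)
    x = rng.normal(loc=3.0, scale=2.0, size=(2, 8, 6, 6))
    y, _ = gn.forward(x)
    yg = y.reshape(2, gn.g, -1)
    np.testing.assert_allclose(yg.mean(axis=2), 0.0, atol=1e-10)
    np.testing.assert_allclose(yg.std(axis=2), 1.0, atol=1e-3)


# -- end-to-end gradients ---------------------------------------------------


def test_full_model_gradients_match_finite_differences(tiny_cfg):
    """Reverse-mode gradients of the composite loss agree with central
    finite differences at sampled parameters of every layer type."""
    net = BilateralSymmetryNet(tiny_cfg, seed=3, dtype=np.float64)
    rng = np.random.default_rng(0)
    xr = rng.random((2, 1, 64, 64))
    xl = rng.random((2, 1, 64, 64))
    yr, yl, ys = np.array([0, 1]), np.array([2, 0]), np.array([2, 1])

    def loss():
        outs, _ = net.forward((xr, xl))
        lr, _ = _ce_and_grad(outs.right_logits, yr)
        ll, _ = _ce_and_grad(outs.left_logits, yl)
        ls, _ = _ce_and_grad(outs.sym_logits, ys)
        return lr + ll + 2 * ls

    zero_grads(net)
    outs, _ = net.forward((xr, xl))
    _, dr = _ce_and_grad(outs.right_logits, yr)
    _, dl = _ce_and_grad(outs.left_logits, yl)
    _, dsym = _ce_and_grad(outs.sym_logits, ys)
    net.backward_outputs(outs, dr, dl, 2 * dsym)

    sampler = np.random.default_rng(7)
    for layer, name in iter_parameters(net):
        flat = layer.params[name].ravel()
        g = layer.grads[name].ravel()
        for idx in sampler.choice(flat.size, size=min(2, flat.size), replace=False):
            eps, old = 1e-6, flat[idx]
            flat[idx] = old + eps
            lp = loss()
            flat[idx] = old - eps
            lm = loss()
            flat[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), (
                f"{type(layer).__name__}.{name}[{idx}]"
            )


def test_conv_matches_scipy_correlate(rng):
    from scipy.signal import correlate2d

    conv = Conv2d(1, 1, 3, 1, rng=rng, dtype=np.float64)
    x = rng.normal(size=(1, 1, 7, 9))
    y, _ = conv.forward(x)
    expected = correlate2d(x[0, 0], conv.params["W"][0, 0], mode="same")
    np.testing.assert_allclose(y[0, 0], expected + conv.params["b"][0], rtol=1e-10)


# -- optimizer --------------------------------------------------------------


def test_rmsprop_update_rule(rng):
    layer = Dense(1, 1, rng=rng, dtype=np.float64)
    layer.params["W"][...] = 2.0
    layer.grads["W"][...] = 0.5
    layer.grads["b"][...] = 0.0
    opt = RMSprop(layer, lr=0.01, rho=0.9, eps=1e-7)
    opt.step()
    v = 0.1 * 0.5**2
    expected = 2.0 - 0.01 * 0.5 / (np.sqrt(v) + 1e-7)
    assert layer.params["W"][0, 0] == pytest.approx(expected, rel=1e-12)


def test_softmax_rows_sum_to_one(rng):
    z = rng.normal(size=(5, 3)) * 10
    p = softmax(z, axis=1)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    np.testing.assert_allclose(softmax(z + 100.0, axis=1), p, atol=1e-9)
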