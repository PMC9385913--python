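"""Autodiff core: every op's gradient against numerical differentiation."""

import numpy as np
import pytest

from contourqa.nn import autograd as ag
from contourqa.nn.autograd import Parameter, Tensor
from contourqa.nn.optim import Adam

RNG = np.random.default_rng(42)


def _numgrad(objective, arr, eps=1e-3):
    g = np.zeros(arr.shape, np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        fp = objective()
        arr[i] = orig - eps
        fm = objective()
        arr[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def _check_grads(build, tensors, tol=5e-2):
    """Backprop a random-projection objective and compare per-element."""
    proj = None

    def objective():
        nonlocal proj
        out = build()
        if proj is None:
            proj = RNG.standard_normal(out.data.shape).astype(np.float32)
        return float((out.data.astype(np.float64) * proj).sum())

    objective()  # fixes proj
    out = build()
    seeded = Tensor(np.array((out.data * proj).sum()), parents=(out,),
                    backward=lambda g: out.accumulate(g * proj))
    for t in tensors.values():
        t.grad = None
    seeded.backward()
    for name, t in tensors.items():
        ng = _numgrad(objective, t.data)
        scale = max(1e-4, np.abs(ng).max())
        assert np.abs(ng - t.grad).max() / scale < tol, f"gradient mismatch: {name}"


def _t(shape, scale=1.0):
    return Tensor((RNG.standard_normal(shape) * scale).astype(np.float32),
                  requires_grad=True)


class TestGradients:
    def test_conv3x3_strided(self):
        x = _t((2, 3, 5, 4, 3))
        w = Parameter(RNG.standard_normal((4, 3, 3, 3, 3)).astype(np.float32) * 0.2)
        b = Parameter(RNG.standard_normal(4).astype(np.float32) * 0.1)
        _check_grads(lambda: ag.conv3x3(x, w, b, (2, 2, 1)),
                     {"x": x, "w": w, "b": b})

    def test_depthwise_conv_strided(self):
        x = _t((2, 3, 5, 4, 4))
        w = Parameter(RNG.standard_normal((3, 3, 3, 3)).astype(np.float32) * 0.3)
        _check_grads(lambda: ag.dwconv3x3(x, w, None, (2, 1, 2)), {"x": x, "w": w})

    def test_conv1x1(self):
        x = _t((2, 4, 3, 3, 2))
        w = Parameter(RNG.standard_normal((5, 4)).astype(np.float32) * 0.3)
        b = Parameter(np.zeros(5, np.float32))
        _check_grads(lambda: ag.conv1x1(x, w, b), {"x": x, "w": w, "b": b})

    def test_batchnorm_training_mode(self):
        x = _t((3, 3, 4, 3, 2))
        gamma = Parameter(RNG.uniform(0.5, 1.5, 3).astype(np.float32))
        beta = Parameter(RNG.standard_normal(3).astype(np.float32))

        def build():
            rm, rv = np.zeros(3), np.ones(3)
            return ag.batchnorm(x, gamma, beta, rm, rv, training=True)

        _check_grads(build, {"x": x, "gamma": gamma, "beta": beta})

    def test_fusion_resize_activations(self):
        x = _t((2, 3, 4, 3, 2))
        y = _t((2, 3, 4, 3, 2))
        w = Parameter(np.array([0.7, 1.3], np.float32))
        _check_grads(lambda: ag.fast_normalized_fusion([x, y], w),
                     {"x": x, "y": y, "w": w})
        _check_grads(lambda: ag.nearest_resize(x, (7, 2, 3)), {"x": x})
        alpha = Parameter(np.array([0.25, 0.1, 0.4], np.float32))
        _check_grads(lambda: ag.prelu(x, alpha), {"x": x, "alpha": alpha})
        _check_grads(lambda: ag.silu(x), {"x": x})
        _check_grads(lambda: ag.sigmoid(x), {"x": x})
        _check_grads(lambda: ag.global_avg_pool(x), {"x": x})

    def test_mse_loss_gradient(self):
        p = _t((6,))
        target = RNG.uniform(0, 1, 6).astype(np.float32)
        loss = ag.mse_loss(p, target)
        loss.backward()
        expected = 2 * (p.data - target) / 6
        assert np.allclose(p.grad, expected, atol=1e-6)


class TestFastNormalizedFusion:
    def test_matches_explicit_loop_oracle(self):
        eps = 1e-4
        inputs = [_t((2, 3, 2, 2, 2)) for _ in range(3)]
        raw = np.array([0.5, -0.2, 2.0], np.float32)  # one negative → rectified
        w = Parameter(raw.copy())
        out = ag.fast_normalized_fusion(inputs, w, eps)
        num = np.zeros_like(inputs[0].data, dtype=np.float64)
        den = eps
        for wi, t in zip(raw, inputs):
            wi = max(0.0, float(wi))
            num += wi * t.data
            den += wi
        assert np.allclose(out.data, num / den, atol=1e-6)

    def test_single_input_weight_one(self):
        x = _t((1, 2, 2, 2, 2))
        w = Parameter(np.array([1.0], np.float32))
        out = ag.fast_normalized_fusion([x], w, 1e-4)
        assert np.allclose(out.data, x.data / (1 + 1e-4), atol=1e-6)

    def test_two_identical_inputs_equal_weights(self):
        x = _t((1, 2, 2, 2, 2))
        w = Parameter(np.array([1.0, 1.0], np.float32))
        out = ag.fast_normalized_fusion([x, x], w, 1e-4)
        assert np.allclose(out.data, x.data, atol=1e-3)

    def test_shape_and_count_mismatches(self):
        x, y = _t((1, 2, 2, 2, 2)), _t((1, 2, 3, 2, 2))
        with pytest.raises(ValueError):
            ag.fast_normalized_fusion([x, y], Parameter(np.ones(2, np.float32)))
        with pytest.raises(ValueError):
            ag.fast_normalized_fusion([x], Parameter(np.ones(2, np.float32)))


def test_adam_minimizes_quadratic():
    p = Parameter(np.array([5.0, -3.0], np.float32))
    opt = Adam([p], lr=0.1)
    for _ in range(300):
        opt.zero_grad()
        loss = ag.mse_loss(p, np.array([1.0, 2.0]))
        loss.backward()
        opt.step()
    assert np.allclose(p.data, [1.0, 2.0], atol=1e-2)


def test_output_strictly_inside_after_clip():
    x = Tensor(np.array([-1e6, 0.0, 1e6], np.float32))
    s = ag.sigmoid(ag.clip(x, -15.0, 15.0)).data
    assert (s > 0).all() and (s < 1).all()
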