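"""Gradient correctness and training mechanics of the NumPy engine.

Finite-difference checks run in float32, so tolerances are loose in
relative terms but every layer is checked against a full numeric
Jacobian-vector product on a small tensor.
"""

import numpy as np
import pytest

from sedseg import nn


def numeric_input_grad(layer, x, dy, eps=1e-2):
    """Central-difference d<dy, layer(x)>/dx, exhaustive over x."""
    g = np.zeros_like(x, dtype=np.float64)
    for idx in np.ndindex(x.shape):
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (np.sum(layer.forward(xp) * dy, dtype=np.float64)
                  - np.sum(layer.forward(xm) * dy, dtype=np.float64)) / (2 * eps)
    return g


def analytic_input_grad(layer, x, dy):
    layer.forward(x)
    for p in layer.params():
        p.zero_grad()
    return layer.backward(dy)


def assert_grads_close(layer, x, dy, rtol=0.05):
    dx = analytic_input_grad(layer, x, dy)
    num = numeric_input_grad(layer, x, dy)
    scale = max(np.abs(num).max(), 1.0)
    np.testing.assert_allclose(dx, num, atol=rtol * scale, rtol=0)


@pytest.fixture
def gen():
    return np.random.default_rng(42)


class TestLayerGradients:
    def test_conv3x3(self, gen):
        layer = nn.Conv2d(3, 5, 3, gen)
        x = gen.standard_normal((2, 6, 6, 3)).astype(np.float32)
        dy = gen.standard_normal((2, 6, 6, 5)).astype(np.float32)
        assert_grads_close(layer, x, dy)

    def test_conv1x1(self, gen):
        layer = nn.Conv2d(4, 2, 1, gen)
        x = gen.standard_normal((2, 5, 5, 4)).astype(np.float32)
        dy = gen.standard_normal((2, 5, 5, 2)).astype(np.float32)
        assert_grads_close(layer, x, dy)

    def test_conv_weight_grad(self, gen):
        layer = nn.Conv2d(2, 3, 3, gen)
        x = gen.standard_normal((2, 6, 6, 2)).astype(np.float32)
        dy = gen.standard_normal((2, 6, 6, 3)).astype(np.float32)
        layer.forward(x)
        for p in layer.params():
            p.zero_grad()
        layer.backward(dy)
        eps = 1e-2
        for idx in [(0, 0, 0, 0), (1, 2, 1, 2), (2, 0, 1, 1)]:
            orig = layer.w.value[idx]
            layer.w.value[idx] = orig + eps
            up = np.sum(layer.forward(x) * dy, dtype=np.float64)
            layer.w.value[idx] = orig - eps
            dn = np.sum(layer.forward(x) * dy, dtype=np.float64)
            layer.w.value[idx] = orig
            assert layer.w.grad[idx] == pytest.approx((up - dn) / (2 * eps), rel=0.02)

    @pytest.mark.parametrize("k", [2, 3])
    def test_conv_transpose_doubles_and_backprops(self, gen, k):
        layer = nn.ConvTranspose2d(3, 4, k, gen)
        x = gen.standard_normal((2, 5, 5, 3)).astype(np.float32)
        y = layer.forward(x)
        assert y.shape == (2, 10, 10, 4)
        dy = gen.standard_normal(y.shape).astype(np.float32)
        assert_grads_close(layer, x, dy)

    def test_maxpool_routes_gradient_to_maxima(self, gen):
        layer = nn.MaxPool2d()
        x = gen.standard_normal((2, 4, 4, 3)).astype(np.float32)
        y = layer.forward(x)
        assert y.shape == (2, 2, 2, 3)
        np.testing.assert_array_equal(
            y, x.reshape(2, 2, 2, 2, 2, 3).max(axis=(2, 4))
        )
        dy = gen.standard_normal(y.shape).astype(np.float32)
        assert_grads_close(layer, x, dy)

    def test_batchnorm_train_mode(self, gen):
        layer = nn.BatchNorm2d(3)
        x = gen.standard_normal((2, 4, 4, 3)).astype(np.float32)
        dy = gen.standard_normal((2, 4, 4, 3)).astype(np.float32)
        assert_grads_close(layer, x, dy)

    def test_batchnorm_eval_uses_running_stats(self, gen):
        layer = nn.BatchNorm2d(2)
        x = gen.standard_normal((4, 3, 3, 2)).astype(np.float32) * 3 + 1
        layer.train_mode = True
        for _ in range(200):
            layer.forward(x)
        layer.train_mode = False
        y = layer.forward(x)
        # after convergence of running stats, eval output is near-normalized
        assert abs(float(y.mean())) < 0.1
        assert 0.8 < float(y.std()) < 1.2

    def test_dense_block_both_modes(self, gen):
        for mode in ("concat_with_input", "new_features_only"):
            layer = nn.DenseBlock(3, 2, 2, mode, dropout=0.0, rng=gen)
            x = gen.standard_normal((2, 4, 4, 3)).astype(np.float32)
            want = 3 + 4 if mode == "concat_with_input" else 4
            y = layer.forward(x)
            assert y.shape == (2, 4, 4, want)
            dy = gen.standard_normal(y.shape).astype(np.float32)
            assert_grads_close(layer, x, dy, rtol=0.08)

    def test_dropout_scales_and_masks(self, gen):
        layer = nn.Dropout(0.5, gen)
        x = np.ones((1, 16, 16, 4), dtype=np.float32)
        layer.train_mode = True
        y = layer.forward(x)
        assert set(np.unique(y)) <= {0.0, 2.0}
        layer.train_mode = False
        np.testing.assert_array_equal(layer.forward(x), x)


class TestOptimizerAndLoss:
    def test_adam_minimizes_quadratic(self):
        p = nn.Param(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(300):
            p.grad[...] = 2 * p.value  # d/dp ||p||^2
            opt.step()
        assert np.abs(p.value).max() < 1e-2

    def test_dice_loss_value_matches_reference(self, gen):
        from sedseg.metrics_losses import dice_loss

        a = gen.random((1, 8, 8, 1)).astype(np.float32)
        b = (gen.random((1, 8, 8, 1)) > 0.5).astype(np.float32)
        loss, _ = nn.dice_loss_and_grad(a, b)
        assert loss == pytest.approx(dice_loss(a[0, ..., 0], b[0, ..., 0]), rel=1e-5)

    def test_dice_grad_matches_numeric(self, gen):
        a = gen.random((2, 4, 4, 1)).astype(np.float32)
        b = (gen.random((2, 4, 4, 1)) > 0.5).astype(np.float32)
        _, grad = nn.dice_loss_and_grad(a, b)
        eps = 1e-3
        for idx in [(0, 1, 2, 0), (1, 3, 0, 0), (0, 0, 0, 0)]:
            ap = a.copy().astype(np.float64)
            ap[idx] += eps
            am = a.copy().astype(np.float64)
            am[idx] -= eps
            lp, _ = nn.dice_loss_and_grad(ap, b)
            lm, _ = nn.dice_loss_and_grad(am, b)
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-2, abs=1e-6)


class TestGraphModel:
    def test_checkpoint_round_trip(self, tiny_sed1, tmp_path, rng):
        x = rng.random((1, 64, 64, 1), dtype=np.float32)
        before = tiny_sed1.forward(x, train=False)
        path = tmp_path / "ckpt.pkl"
        tiny_sed1.save(path)
        from sedseg.nn import GraphModel

        loaded = GraphModel.load(path)
        np.testing.assert_array_equal(loaded.forward(x, train=False), before)

    def test_state_dict_restores_exactly(self, gen, tiny_sed1, rng):
        x = rng.random((1, 64, 64, 1), dtype=np.float32)
        state = tiny_sed1.state_dict()
        before = tiny_sed1.forward(x, train=False)
        for p in tiny_sed1.params():
            p.value += gen.standard_normal(p.value.shape).astype(np.float32) * 0.1
        assert not np.array_equal(tiny_sed1.forward(x, train=False), before)
        tiny_sed1.load_state_dict(state)
        np.testing.assert_array_equal(tiny_sed1.forward(x, train=False), before)
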