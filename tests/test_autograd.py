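"""Gradient checks for the autograd engine against central finite differences."""

import numpy as np
import pytest

from pomonet import nn
from pomonet.autograd import Tensor, concat, conv1d, max_pool1d, softmax


def finite_difference(f, params, eps=1e-6):
    """Central-difference gradients of scalar f() w.r.t. each parameter."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        flat = p.data.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = f()
            flat[i] = orig - eps
            lo = f()
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads


def check_module_gradients(module, x, atol=1e-6):
    params = module.parameters()

    def loss_value():
        out = module(Tensor(x))
        return float((out.data ** 2).sum())

    out = module(Tensor(x))
    loss = (out * out).sum()
    for p in params:
        p.grad = None
    loss.backward()
    numeric = finite_difference(loss_value, params)
    for p, num in zip(params, numeric):
        np.testing.assert_allclose(p.grad, num, atol=atol, rtol=1e-4)


class TestOps:
    def test_add_mul_broadcast(self, rng):
        a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(4,)), requires_grad=True)
        out = ((a + b) * a).sum()
        out.backward()
        np.testing.assert_allclose(a.grad, 2 * a.data + b.data)
        np.testing.assert_allclose(b.grad, a.data.sum(axis=0))

    def test_matmul_batched(self, rng):
        a = Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
        b = Tensor(rng.normal(size=(2, 4, 5)), requires_grad=True)
        (a @ b).sum().backward()
        assert a.grad.shape == (2, 3, 4)
        assert b.grad.shape == (2, 4, 5)

    def test_mean_over_tuple_axes(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 4)), requires_grad=True)
        x.mean(axis=(0, 2)).sum().backward()
        np.testing.assert_allclose(x.grad, np.full((2, 3, 4), 1.0 / 8))

    def test_getitem_gradient_accumulates(self, rng):
        x = Tensor(rng.normal(size=(5,)), requires_grad=True)
        (x[1] + x[1] + x[3]).backward()
        np.testing.assert_allclose(x.grad, [0, 2, 0, 1, 0])

    def test_softmax_rows_sum_to_one(self, rng):
        out = softmax(Tensor(rng.normal(size=(4, 6)) * 50))
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0)
        assert np.all(np.isfinite(out.data))

    def test_concat_backward_splits(self, rng):
        a = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=(2, 2)), requires_grad=True)
        (concat([a, b], axis=1) * 2).sum().backward()
        np.testing.assert_allclose(a.grad, 2.0)
        np.testing.assert_allclose(b.grad, 2.0)

    def test_max_pool_forward_and_routing(self):
        x = Tensor(np.array([[[1.0, 5.0, 2.0, 3.0]]]), requires_grad=True)
        out = max_pool1d(x, 2)
        np.testing.assert_allclose(out.data, [[[5.0, 3.0]]])
        out.sum().backward()
        np.testing.assert_allclose(x.grad, [[[0, 1, 0, 1]]])

    def test_conv1d_matches_direct_convolution(self, rng):
        x = rng.normal(size=(1, 2, 6))
        w = rng.normal(size=(3, 2, 3))
        b = rng.normal(size=3)
        out = conv1d(Tensor(x), Tensor(w), Tensor(b), pad=1)
        # direct computation
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1)))
        for f in range(3):
            for t in range(6):
                ref = (xp[0, :, t:t + 3] * w[f]).sum() + b[f]
                assert out.data[0, f, t] == pytest.approx(ref)


class TestLayerGradients:
    def test_dense(self, rng):
        check_module_gradients(nn.Dense(4, 3, rng), rng.normal(size=(5, 4)))

    def test_conv(self, rng):
        check_module_gradients(nn.Conv1d(2, 3, 3, rng),
                               rng.normal(size=(2, 2, 7)))

    def test_gru_forward_and_reverse(self, rng):
        for reverse in (False, True):
            check_module_gradients(nn.GRU(1, 4, rng, reverse=reverse),
                                   rng.normal(size=(2, 5, 1)), atol=1e-5)

    def test_attention(self, rng):
        check_module_gradients(nn.SelfAttention(6, 6, rng),
                               rng.normal(size=(2, 5)), atol=1e-5)

    def test_batchnorm_training_mode(self, rng):
        bn = nn.BatchNorm1d(3)
        bn.set_training(True)
        check_module_gradients(bn, rng.normal(size=(4, 3, 5)), atol=1e-5)

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = nn.BatchNorm1d(2)
        bn.set_training(True)
        x = rng.normal(2.0, 3.0, size=(8, 2, 4))
        for _ in range(200):
            bn(Tensor(x))
        bn.set_training(False)
        out = bn(Tensor(x)).data
        # after convergence of running stats, eval output ~ normalized
        assert abs(out.mean()) < 0.05
        assert abs(out.std() - 1.0) < 0.1


class TestOptimizer:
    def test_adam_minimizes_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([p], l2_factor=0.0)
        for _ in range(500):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step(0.05)
        assert np.abs(p.data).max() < 1e-3

    def test_l2_applies_only_to_decay_parameters(self):
        decayed = nn.Parameter(np.array([1.0]), decay=True)
        frozen = nn.Parameter(np.array([1.0]), decay=False)
        opt = nn.Adam([decayed, frozen], l2_factor=0.5)
        loss = (decayed * 0.0 + frozen * 0.0).sum()
        opt.zero_grad()
        loss.backward()
        opt.step(0.1)
        assert decayed.data[0] < 1.0   # pulled toward zero by L2
        assert frozen.data[0] == pytest.approx(1.0)

    def test_dropout_inverted_scaling(self, rng):
        drop = nn.Dropout(0.4, rng)
        drop.set_training(True)
        x = np.ones((200, 50))
        out = drop(Tensor(x)).data
        kept = out[out > 0]
        assert np.allclose(kept, 1.0 / 0.6)
        assert abs(out.mean() - 1.0) < 0.05
        drop.set_training(False)
        np.testing.assert_allclose(drop(Tensor(x)).data, x)
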