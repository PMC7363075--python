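"""Engine correctness: numerical gradient checks and layer contracts."""
import numpy as np
import pytest

from strokect.nn import (Adam, DualPathwayDenseNet, Tensor, UNet,
                         bce_with_logits, conv_nd, dice_loss_batch_tensor,
                         maxpool_nd, mean_all, relu, sigmoid, softmax,
                         softmax_crossentropy, upsample_nd)
from strokect.nn.layers import BatchNorm
from strokect.nn.tensor import _corr_nd


def _numgrad(f, arr, eps=1e-3):
    g = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        lp = f()
        arr[i] = orig - eps
        lm = f()
        arr[i] = orig
        g[i] = (lp - lm) / (2 * eps)
    return g


def _relerr(a, b):
    return np.abs(a - b).max() / (np.abs(a).max() + 1e-9)


class TestGradients:
    def test_conv2d_matches_numerical_gradient(self, rng):
        x = Tensor(rng.normal(size=(2, 2, 6, 6)).astype(np.float32), requires_grad=True)
        w = Tensor(rng.normal(size=(3, 2, 3, 3)).astype(np.float32) * 0.5,
                   requires_grad=True)
        b = Tensor(rng.normal(size=3).astype(np.float32), requires_grad=True)
        mean_all(relu(conv_nd(x, w, b))).backward()

        def f():
            out = _corr_nd(x.data, w.data) + b.data.reshape(1, -1, 1, 1)
            return float(np.maximum(out, 0).mean())

        for t in (x, w, b):
            assert _relerr(_numgrad(f, t.data), t.grad) < 5e-3

    def test_conv3d_matches_numerical_gradient(self, rng):
        x = Tensor(rng.normal(size=(2, 2, 3, 4, 4)).astype(np.float32),
                   requires_grad=True)
        w = Tensor(rng.normal(size=(2, 2, 3, 3, 3)).astype(np.float32) * 0.5,
                   requires_grad=True)
        mean_all(conv_nd(x, w)).backward()
        f = lambda: float(_corr_nd(x.data, w.data).mean())
        for t in (x, w):
            assert _relerr(_numgrad(f, t.data), t.grad) < 5e-3

    def test_pool_upsample_gradients(self, rng):
        x = Tensor(rng.normal(size=(2, 2, 4, 6)).astype(np.float32), requires_grad=True)
        mean_all(maxpool_nd(x, (2, 2))).backward()
        f = lambda: float(x.data.reshape(2, 2, 2, 2, 3, 2).max(axis=(3, 5)).mean())
        assert _relerr(_numgrad(f, x.data), x.grad) < 5e-3

        y = Tensor(rng.normal(size=(2, 2, 3, 3)).astype(np.float32), requires_grad=True)
        mean_all(upsample_nd(y, (2, 2))).backward()
        g = lambda: float(np.repeat(np.repeat(y.data, 2, 2), 2, 3).mean())
        assert _relerr(_numgrad(g, y.data), y.grad) < 5e-3

    def test_loss_gradients(self, rng):
        x = Tensor(rng.normal(size=(2, 1, 4, 4)).astype(np.float32), requires_grad=True)
        y = (rng.random((2, 1, 4, 4)) > 0.5).astype(np.float32)
        bce_with_logits(x, y).backward()

        def f_bce():
            z = x.data
            return float((np.maximum(z, 0) - z * y
                          + np.log1p(np.exp(-np.abs(z)))).mean())

        assert _relerr(_numgrad(f_bce, x.data), x.grad) < 5e-3

        s = Tensor(rng.normal(size=(3, 1, 5, 5)).astype(np.float32), requires_grad=True)
        t = (rng.random((3, 1, 5, 5)) > 0.6).astype(np.float32)
        dice_loss_batch_tensor(sigmoid(s), t).backward()

        def f_dice():
            p = 1 / (1 + np.exp(-s.data))
            num = 2 * (p * t).sum(axis=(1, 2, 3)) + 1e-6
            den = (p * p + t * t).sum(axis=(1, 2, 3)) + 1e-6
            return float((1 - num / den).mean())

        assert _relerr(_numgrad(f_dice, s.data), s.grad) < 5e-3

        z = Tensor(rng.normal(size=(4, 2)).astype(np.float32), requires_grad=True)
        oh = np.eye(2, dtype=np.float32)[rng.integers(0, 2, 4)]
        softmax_crossentropy(z, oh).backward()

        def f_ce():
            a = z.data
            m = a.max(axis=1, keepdims=True)
            lp = a - (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True)))
            return float(-(oh * lp).sum() / 4)

        assert _relerr(_numgrad(f_ce, z.data), z.grad) < 5e-3

    def test_batchnorm_training_gradient(self, rng):
        from strokect.nn.tensor import batchnorm

        x = Tensor(rng.normal(size=(4, 3, 5)).astype(np.float32), requires_grad=True)
        gamma = Tensor(np.abs(rng.normal(size=3)).astype(np.float32) + 0.5,
                       requires_grad=True)
        beta = Tensor(rng.normal(size=3).astype(np.float32), requires_grad=True)
        rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
        mean_all(relu(batchnorm(x, gamma, beta, rm.copy(), rv.copy(),
                                0.99, 1e-3, True))).backward()

        def f():
            mu = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            xh = (x.data - mu.reshape(1, -1, 1)) / np.sqrt(var.reshape(1, -1, 1) + 1e-3)
            return float(np.maximum(gamma.data.reshape(1, -1, 1) * xh
                                    + beta.data.reshape(1, -1, 1), 0).mean())

        for t in (x, gamma, beta):
            assert _relerr(_numgrad(f, t.data), t.grad) < 5e-3


class TestUNet:
    def test_forward_shape_and_sigmoid_range(self, rng):
        net = UNet(1, (4, 8), (5, 5), (16, 16), seed=0)
        prob = net.predict_proba(rng.random((2, 16, 16)).astype(np.float32))
        assert prob.shape == (2, 16, 16)
        assert np.all((prob > 0) & (prob < 1))

    def test_seeded_builds_identical(self):
        a = UNet(1, (4, 8), (3, 3, 3), (4, 8, 8), seed=7)
        b = UNet(1, (4, 8), (3, 3, 3), (4, 8, 8), seed=7)
        for k, v in a.state_dict().items():
            np.testing.assert_array_equal(v, b.state_dict()[k])

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UNet(1, (4, 8, 16), (5, 5), (10, 10), seed=0)

    def test_state_roundtrip(self, rng, tmp_path):
        net = UNet(1, (4, 8), (5, 5), (16, 16), seed=3)
        x = rng.random((1, 16, 16)).astype(np.float32)
        ref = net.predict_proba(x)
        np.savez(tmp_path / "w.npz", **net.state_dict())
        other = UNet(1, (4, 8), (5, 5), (16, 16), seed=99)
        with np.load(tmp_path / "w.npz") as data:
            other.load_state_dict(dict(data))
        np.testing.assert_allclose(other.predict_proba(x), ref, rtol=1e-6)


class TestDualPathway:
    def test_softmax_output_and_determinism(self, rng):
        net = DualPathwayDenseNet(stem_filters=4, blocks=2, layers_per_block=1,
                                  growth=2, hidden_units=8, seed=0)
        f = rng.random((3, 3, 32, 32)).astype(np.float32)
        c = rng.random((3, 3, 32, 32)).astype(np.float32)
        p = net.predict_proba(f, c)
        assert p.shape == (3, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)
        # dropout disabled at inference: repeated calls identical
        np.testing.assert_array_equal(p, net.predict_proba(f, c))
        # duplicated patch gets an identical probability
        f2 = np.concatenate([f, f[:1]])
        c2 = np.concatenate([c, c[:1]])
        p2 = net.predict_proba(f2, c2)
        np.testing.assert_allclose(p2[0], p2[3], atol=1e-6)

    def test_dense_block_channel_growth(self):
        net = DualPathwayDenseNet(stem_filters=4, blocks=1, layers_per_block=3,
                                  growth=2, hidden_units=8, seed=0)
        blk = net.fine_path.blocks[0]
        in_channels = [conv.w.data.shape[1] for conv in blk.convs]
        assert in_channels == [4, 6, 8]  # each layer sees all previous outputs

    def test_batch_permutation_permutes_outputs(self, rng):
        net = DualPathwayDenseNet(stem_filters=4, blocks=2, layers_per_block=1,
                                  growth=2, hidden_units=8, seed=1)
        f = rng.random((4, 3, 32, 32)).astype(np.float32)
        c = rng.random((4, 3, 32, 32)).astype(np.float32)
        p = net.predict_proba(f, c)
        perm = np.array([2, 0, 3, 1])
        p_perm = net.predict_proba(f[perm], c[perm])
        np.testing.assert_allclose(p_perm, p[perm], atol=2e-5)


def test_adam_reduces_quadratic_loss():
    w = Tensor(np.array([5.0, -3.0], np.float32), requires_grad=True)
    opt = Adam([w], lr=0.1)
    for _ in range(200):
        loss = mean_all(w * w)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(w.data).max() < 0.5
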