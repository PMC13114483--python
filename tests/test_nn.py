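"""Autograd engine, attention blocks, losses and training mechanics."""

import numpy as np
import pytest

from sfdibruise import nn
from sfdibruise.nn.autograd import Tensor, concat, no_grad


def numeric_grad(f, x, i, eps=1e-6):
    x.data[i] += eps
    hi = f().data
    x.data[i] -= 2 * eps
    lo = f().data
    x.data[i] += eps
    return (hi - lo) / (2 * eps)


class TestAutograd:
    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
        conv = nn.Conv2d(3, 4, 3, stride=2, padding=1, rng=rng)
        out = conv(x).sigmoid().mean()
        out.backward()
        for idx in [(0, 1, 0, 0), (3, 2, 2, 2)]:
            num = numeric_grad(lambda: conv(Tensor(x.data)).sigmoid().mean(),
                              conv.weight, idx)
            assert conv.weight.grad[idx] == pytest.approx(num, rel=1e-5, abs=1e-9)
        gx = x.grad.copy()
        xi = (1, 2, 3, 3)

        def f():
            return conv(Tensor(x.data)).sigmoid().mean()

        assert gx[xi] == pytest.approx(numeric_grad(f, x, xi), rel=1e-5, abs=1e-9)

    def test_composite_expression_gradient(self):
        rng = np.random.default_rng(1)
        a = Tensor(rng.normal(size=(4, 5)), requires_grad=True)
        b = Tensor(rng.normal(size=(4, 5)), requires_grad=True)
        out = ((a * b).tanh() + (a - b).abs()).mean()
        out.backward()
        idx = (2, 3)

        def f():
            aa, bb = Tensor(a.data), Tensor(b.data)
            return ((aa * bb).tanh() + (aa - bb).abs()).mean()

        assert a.grad[idx] == pytest.approx(numeric_grad(f, a, idx), rel=1e-5)

    def test_amax_routes_gradient_to_argmax(self):
        x = Tensor(np.array([[1.0, 5.0, 2.0]]), requires_grad=True)
        x.amax(axis=1, keepdims=True).sum().backward()
        np.testing.assert_array_equal(x.grad, [[0.0, 1.0, 0.0]])

    def test_upsample_round_trip_shapes(self):
        x = Tensor(np.random.default_rng(2).normal(size=(1, 2, 4, 4)),
                   requires_grad=True)
        up = x.upsample2x()
        assert up.shape == (1, 2, 8, 8)
        up.mean().backward()
        assert x.grad.shape == x.shape

    def test_no_grad_disables_recording(self):
        x = Tensor(np.ones((2, 2)), requires_grad=True)
        with no_grad():
            y = (x * 2).mean()
        assert not y.requires_grad


class TestPairAssembly:
    def test_lossless_round_trip(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (16, 16, 3))
        y = rng.uniform(0, 1, (16, 16, 3))
        comp = nn.assemble_pair(x, y)
        assert comp.shape == (16, 32, 3)
        x2, y2 = nn.split_pair(comp)
        np.testing.assert_array_equal(x2, x)
        np.testing.assert_array_equal(y2, y)

    def test_mismatched_heights_rejected(self):
        with pytest.raises(ValueError):
            nn.assemble_pair(np.zeros((8, 8)), np.zeros((9, 8)))


class TestAttention:
    def test_channel_weights_in_unit_interval(self):
        ca = nn.ChannelAttention(8, reduction=4, rng=np.random.default_rng(4))
        x = Tensor(np.random.default_rng(5).normal(size=(2, 8, 6, 6)))
        w = ca.weights(x)
        assert w.shape == (2, 8, 1, 1)
        assert np.all((w.data > 0) & (w.data < 1))
        assert ca(x).shape == x.shape

    def test_channel_reduction_clipped_for_narrow_layers(self):
        ca = nn.ChannelAttention(4, reduction=16)
        assert ca.fc1.weight.shape[0] >= 1

    def test_constant_features_equalize_pooling_paths(self):
        ca = nn.ChannelAttention(4, reduction=2, rng=np.random.default_rng(6))
        x = Tensor(np.ones((1, 4, 5, 5)) * np.arange(1, 5).reshape(1, 4, 1, 1))
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.amax(axis=(2, 3), keepdims=True)
        np.testing.assert_array_equal(avg.data, mx.data)

    def test_spatial_weights_shape_and_range(self):
        sa = nn.SpatialAttention(kernel=7, rng=np.random.default_rng(7))
        x = Tensor(np.random.default_rng(8).normal(size=(2, 6, 8, 8)))
        w = sa.weights(x)
        assert w.shape == (2, 1, 8, 8)
        assert np.all((w.data > 0) & (w.data < 1))

    def test_spatial_statistics_invariant_to_channel_permutation(self):
        rng = np.random.default_rng(9)
        sa = nn.SpatialAttention(kernel=3, rng=rng)
        x = rng.normal(size=(1, 5, 6, 6))
        perm = x[:, [3, 0, 4, 1, 2]]
        w1 = sa.weights(Tensor(x)).data
        w2 = sa.weights(Tensor(perm)).data
        np.testing.assert_allclose(w1, w2, atol=1e-12)


class TestArchitecture:
    def test_generator_shapes_and_cbam_count(self):
        cfg = nn.GeneratorConfig(depth=3, base_channels=4)
        gen = nn.build_generator(cfg, seed=0)
        assert gen.n_cbam == 2 * cfg.depth
        out = gen(Tensor(np.random.default_rng(10).normal(size=(1, 1, 32, 32))))
        assert out.shape == (1, 3, 32, 32)
        assert np.isfinite(out.data).all()
        assert np.all((out.data > 0) & (out.data < 1))

    def test_generator_deterministic_forward(self):
        gen = nn.build_generator(nn.GeneratorConfig(depth=2, base_channels=4), seed=1)
        x = Tensor(np.random.default_rng(11).normal(size=(1, 1, 16, 16)))
        np.testing.assert_array_equal(gen(x).data, gen(x).data)

    def test_discriminator_patch_grid(self):
        disc = nn.build_discriminator(nn.DiscriminatorConfig(), seed=2)
        rng = np.random.default_rng(12)
        out = disc(Tensor(rng.normal(size=(2, 1, 32, 32))),
                   Tensor(rng.normal(size=(2, 3, 32, 32))))
        assert out.data.ndim == 4
        assert np.all((out.data > 0) & (out.data < 1))

    def test_depth_below_two_rejected(self):
        with pytest.raises(ValueError):
            nn.GeneratorConfig(depth=1)


class TestLosses:
    def test_symmetric_discriminator_value(self):
        half = Tensor(np.full((2, 1, 4, 4), 0.5))
        loss = nn.gan_loss(half, half)
        assert loss.data == pytest.approx(-2 * np.log(2), rel=1e-12)

    def test_perfect_discriminator_limit(self):
        ones = Tensor(np.ones((1, 1, 2, 2)))
        zeros = Tensor(np.zeros((1, 1, 2, 2)))
        loss = nn.gan_loss(ones, zeros)
        assert abs(loss.data) < 1e-5  # clamped at epsilon, not exactly 0

    def test_batch_permutation_invariance(self):
        rng = np.random.default_rng(13)
        d = rng.uniform(0.1, 0.9, (4, 1, 3, 3))
        l1 = nn.gan_loss(Tensor(d), Tensor(d[::-1].copy()))
        l2 = nn.gan_loss(Tensor(d[::-1].copy()), Tensor(d))
        assert l1.data == pytest.approx(l2.data)

    def test_l1_and_composite_arithmetic(self):
        y = Tensor(np.zeros((2, 3, 4, 4)))
        assert nn.l1_loss(y, y).data == 0.0
        gan = Tensor(np.array(1.0))
        l1 = Tensor(np.array(0.5))
        assert nn.total_loss(gan, l1, 60.0).data == pytest.approx(31.0)
        assert nn.total_loss(gan, l1, 120.0).data - nn.total_loss(
            gan, l1, 60.0
        ).data == pytest.approx(30.0)

    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            nn.TrainConfig(lambda_l1=0.0)


class TestTrainingMechanics:
    def test_split_tags_disjoint(self, smoke_dataset):
        manifest, _ = smoke_dataset
        train_inputs = {e["input"] for e in manifest.paths("train")}
        val_inputs = {e["input"] for e in manifest.paths("val")}
        assert not train_inputs & val_inputs
        assert len(train_inputs) + len(val_inputs) == len(manifest.entries)

    def test_two_epoch_history_and_reproducibility(self, smoke_dataset):
        manifest, root = smoke_dataset
        cfg = nn.TrainConfig(epochs=2, seed=5, learning_rate=1e-3)
        gen_cfg = nn.GeneratorConfig(depth=2, base_channels=4)
        _, h1 = nn.train(manifest, root, cfg, gen_cfg)
        _, h2 = nn.train(manifest, root, cfg, gen_cfg)
        assert len(h1.val_l1) == 2
        assert h1.val_l1 == h2.val_l1
        assert h1.train_total == h2.train_total

    def test_checkpoint_round_trip(self, smoke_dataset, tmp_path):
        gen = nn.build_generator(nn.GeneratorConfig(depth=2, base_channels=4), seed=3)
        path = tmp_path / "gen.npz"
        nn.save_checkpoint(path, gen)
        gen2 = nn.load_checkpoint(path)
        x = Tensor(np.random.default_rng(14).normal(size=(1, 1, 16, 16)))
        np.testing.assert_array_equal(gen(x).data, gen2(x).data)

    def test_predict_output_within_label_ranges(self):
        gen = nn.build_generator(nn.GeneratorConfig(depth=2, base_channels=4), seed=4)
        rd = np.random.default_rng(15).uniform(0, 1, (16, 16))
        est = nn.predict(gen, rd, pixel_size=1.0)
        assert est.mu_a.max() <= 0.5
        assert est.mu_s_prime.max() <= 4.0

    def test_predict_rejects_incompatible_size(self):
        gen = nn.build_generator(nn.GeneratorConfig(depth=3, base_channels=4), seed=5)
        with pytest.raises(ValueError):
            nn.predict(gen, np.zeros((10, 10)), 1.0)
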