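import numpy as np
import pytest

from wedseg.network import (NetworkConfig, SegmentationNet, _Bottleneck,
                            _DecoderBlock, _EncoderBlock, build_layer_specs,
                            count_parameters, softmax_channels)
from wedseg.nn import Conv2d, ConvTranspose2d, MaxPool2x2


def _toy_config(**kw):
    base = dict(in_channels=3, base_width=2, depth=2, bottleneck_width=8,
                num_classes=3, dropout_rates=(0.1, 0.2))
    base.update(kw)
    return NetworkConfig(**base)


class TestConfig:
    def test_dropout_rate_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(dropout_rates=(0.4, 0.3, 0.2, 0.1))
        with pytest.raises(ValueError):
            NetworkConfig(dropout_rates=(0.1, 0.2, 0.3))
        with pytest.raises(ValueError):
            NetworkConfig(bottleneck_width=64)

    def test_encoder_widths_doubling(self):
        assert NetworkConfig().encoder_widths == (8, 16, 32, 64)


class TestParameterCount:
    def test_default_two_class_head(self):
        """The default channel plan (8/16/32/64, bottleneck 128, biases
        everywhere, no batch norm) with a 2-channel head totals 485,826
        trainable parameters."""
        specs = build_layer_specs(NetworkConfig(num_classes=2))
        assert count_parameters(specs) == 485_826

    def test_default_three_class_head(self):
        """The 3-class head adds 8*3+3 - (8*2+2) = 9 parameters."""
        specs = build_layer_specs(NetworkConfig(num_classes=3))
        assert count_parameters(specs) == 485_835

    def test_toy_depth_one(self):
        config = NetworkConfig(in_channels=1, base_width=1, depth=1,
                               bottleneck_width=2, num_classes=2,
                               dropout_rates=(0.1,))
        assert count_parameters(build_layer_specs(config)) == 120

    def test_spec_count_matches_actual_weights(self):
        for num_classes in (2, 3):
            net = SegmentationNet(NetworkConfig(num_classes=num_classes))
            assert net.n_parameters() == count_parameters(net.layer_specs())

    def test_count_invariant_to_input_size(self):
        net = SegmentationNet(_toy_config())
        before = net.n_parameters()
        net.forward(np.zeros((1, 3, 16, 16)))
        net.forward(np.zeros((1, 3, 32, 32)))
        assert net.n_parameters() == before

    def test_doubling_base_width_quadruples_count(self):
        small = count_parameters(build_layer_specs(NetworkConfig(num_classes=2)))
        big = count_parameters(build_layer_specs(
            NetworkConfig(base_width=16, bottleneck_width=256, num_classes=2)))
        assert big > 3.8 * small

    def test_batch_norm_changes_count(self):
        plain = count_parameters(build_layer_specs(NetworkConfig()))
        bn = count_parameters(build_layer_specs(NetworkConfig(use_batch_norm=True)))
        assert bn > plain


class TestPrimitives:
    def test_maxpool_single_block(self):
        x = np.array([[1, 2], [3, 4]], dtype=float)[None, None]
        np.testing.assert_array_equal(MaxPool2x2().forward(x), [[[[4]]]])

    def test_maxpool_enumerated_blocks(self):
        x = np.arange(1, 17, dtype=float).reshape(1, 1, 4, 4)
        np.testing.assert_array_equal(MaxPool2x2().forward(x)[0, 0],
                                      [[6, 8], [14, 16]])

    def test_maxpool_constant(self):
        x = np.full((1, 2, 4, 4), 7.0)
        out = MaxPool2x2().forward(x)
        assert out.shape == (1, 2, 2, 2) and (out == 7.0).all()

    def test_maxpool_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            MaxPool2x2().forward(np.zeros((1, 1, 3, 4)))

    def test_conv_same_padding_shape(self):
        conv = Conv2d(2, 5, 3, rng=np.random.default_rng(0))
        assert conv.forward(np.zeros((1, 2, 8, 8))).shape == (1, 5, 8, 8)

    def test_transpose_doubles_spatial(self):
        up = ConvTranspose2d(4, 2, rng=np.random.default_rng(0))
        assert up.forward(np.zeros((1, 4, 1, 1))).shape == (1, 2, 2, 2)


class TestBlocks:
    def test_encoder_zero_weights_identity_on_shortcut(self):
        """With every weight and bias zero the block output equals the
        second conv's input (ReLU(0) + y = y)."""
        rng = np.random.default_rng(0)
        block = _EncoderBlock(1, 1, 0.0, False, rng, np.float64)
        for unit in (block.unit1, block.unit2):
            unit.conv.params["W"][:] = 0
            unit.conv.params["b"][:] = 0
        out = block.forward(np.ones((1, 1, 4, 4)), False, None)
        np.testing.assert_array_equal(out, np.zeros((1, 1, 4, 4)))

    def test_encoder_scalar_residual_arithmetic(self):
        """Scalar toy of the residual rule H(x) = f(wx+b) + x: with the
        second conv's center weight 1.5 and input 2, H = ReLU(3) + 2 = 5."""
        rng = np.random.default_rng(0)
        block = _EncoderBlock(1, 1, 0.0, False, rng, np.float64)
        # first conv passes x through unchanged (identity kernel)
        block.unit1.conv.params["W"][:] = 0
        block.unit1.conv.params["W"][0, 0, 1, 1] = 1.0
        block.unit1.conv.params["b"][:] = 0
        block.unit2.conv.params["W"][:] = 0
        block.unit2.conv.params["W"][0, 0, 1, 1] = 1.5
        block.unit2.conv.params["b"][:] = 0
        out = block.forward(np.full((1, 1, 1, 1), 2.0), False, None)
        assert out[0, 0, 0, 0] == pytest.approx(5.0)

    def test_bottleneck_zero_weights_zero_output(self):
        rng = np.random.default_rng(0)
        block = _Bottleneck(1, 2, 0.0, False, rng, np.float64)
        for unit in (block.unit1, block.unit2):
            unit.conv.params["W"][:] = 0
            unit.conv.params["b"][:] = 0
        out = block.forward(np.ones((1, 1, 4, 4)), False, None)
        assert (out == 0).all()

    def test_bottleneck_identity_kernels_pass_through(self):
        """Identity 3x3 kernels with zero bias reproduce a non-negative
        input exactly (no shortcut in the bottleneck)."""
        rng = np.random.default_rng(0)
        block = _Bottleneck(1, 1, 0.0, False, rng, np.float64)
        for unit in (block.unit1, block.unit2):
            unit.conv.params["W"][:] = 0
            unit.conv.params["W"][0, 0, 1, 1] = 1.0
            unit.conv.params["b"][:] = 0
        x = np.abs(np.random.default_rng(1).random((1, 1, 3, 3)))
        np.testing.assert_allclose(block.forward(x, False, None), x)

    def test_decoder_zero_weights_zero_output(self):
        rng = np.random.default_rng(0)
        block = _DecoderBlock(4, 2, 0.0, False, rng, np.float64)
        block.up.params["W"][:] = 0
        block.up.params["b"][:] = 0
        for unit in (block.unit1, block.unit2):
            unit.conv.params["W"][:] = 0
            unit.conv.params["b"][:] = 0
        skip = np.random.default_rng(2).random((1, 2, 8, 8))
        out = block.forward(np.ones((1, 4, 4, 4)), skip, False, None)
        assert (out == 0).all()

    def test_decoder_concat_channels(self):
        rng = np.random.default_rng(0)
        block = _DecoderBlock(4, 2, 0.0, False, rng, np.float64)
        out = block.forward(np.ones((1, 4, 4, 4)), np.ones((1, 2, 8, 8)),
                            False, None)
        assert out.shape == (1, 2, 8, 8)


class TestForward:
    def test_output_shape_and_simplex(self):
        net = SegmentationNet(_toy_config(), seed=0)
        x = np.random.default_rng(0).random((2, 3, 16, 16))
        probs = net.forward(x)
        assert probs.shape == (2, 3, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_default_input_contract(self):
        net = SegmentationNet(NetworkConfig(), seed=0)
        probs = net.forward(np.zeros((1, 3, 128, 128)))
        assert probs.shape == (1, 3, 128, 128)

    def test_bottleneck_spatial_size(self):
        """128 / 2^4 = 8: four poolings shrink the map to 8x8."""
        net = SegmentationNet(NetworkConfig(), seed=0)
        x = np.random.default_rng(0).random((1, 3, 128, 128))
        skips = []
        h = x
        for block, pool in zip(net.encoder, net.pools):
            s = block.forward(h, False, None)
            skips.append(s)
            h = pool.forward(s, False, None)
        bott = net.bottleneck.forward(h, False, None)
        assert bott.shape[2:] == (8, 8)

    def test_indivisible_size_rejected(self):
        net = SegmentationNet(_toy_config(), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 3, 18, 18)))

    def test_zero_parameters_give_uniform_map(self):
        net = SegmentationNet(_toy_config(), seed=0)
        net.set_weights([np.zeros_like(w) for w in net.get_weights()])
        probs = net.forward(np.random.default_rng(0).random((1, 3, 16, 16)))
        np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-12)

    def test_softmax_closed_form(self):
        logits = np.array([2.0, 0.0, 0.0]).reshape(1, 3, 1, 1)
        probs = softmax_channels(logits)[0, :, 0, 0]
        e2 = np.exp(2.0)
        np.testing.assert_allclose(probs, [e2 / (e2 + 2), 1 / (e2 + 2),
                                           1 / (e2 + 2)], atol=1e-9)
        assert probs[0] == pytest.approx(0.787, abs=5e-4)

    def test_inference_deterministic(self):
        net = SegmentationNet(_toy_config(), seed=0)
        x = np.random.default_rng(0).random((1, 3, 16, 16))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_checkpoint_roundtrip(self, tmp_path):
        net = SegmentationNet(_toy_config(), seed=5)
        path = tmp_path / "ckpt.npz"
        net.save(path)
        loaded = SegmentationNet.load(path)
        x = np.random.default_rng(0).random((1, 3, 16, 16))
        np.testing.assert_allclose(loaded.forward(x), net.forward(x), atol=1e-12)


class TestGradients:
    def test_autodiff_matches_finite_differences(self):
        """Central finite differences agree with backprop to < 1e-4 relative
        error on 10 sampled parameters of a 16x16 toy network.  Biases are
        set to small random values first so no ReLU argument sits exactly
        at the kink, where the loss is not differentiable."""
        from wedseg.train import dice_ce_loss_grad, one_hot_encode

        rng = np.random.default_rng(7)
        net = SegmentationNet(_toy_config(), seed=3)
        for _, name, layer in net.param_items():
            if name == "b":
                layer.params[name] = rng.normal(0, 0.1, layer.params[name].shape)
        x = rng.random((2, 3, 16, 16))
        t = np.stack([one_hot_encode(m, 3)
                      for m in rng.integers(0, 3, (2, 16, 16))])

        def loss_fn():
            drop_rng = np.random.default_rng(99)
            logits = net.forward_logits(x, training=True, rng=drop_rng)
            return dice_ce_loss_grad(logits, t)

        loss, dlogits, _ = loss_fn()
        net.backward(dlogits)
        items = list(net.param_items())
        check = np.random.default_rng(5)
        for _ in range(10):
            _, name, layer = items[check.integers(len(items))]
            arr = layer.params[name]
            idx = np.unravel_index(check.integers(arr.size), arr.shape)
            h, orig = 1e-6, arr[idx]
            arr[idx] = orig + h
            lp, _, _ = loss_fn()
            arr[idx] = orig - h
            lm, _, _ = loss_fn()
            arr[idx] = orig
            fd = (lp - lm) / (2 * h)
            analytic = layer.grads[name][idx]
            assert abs(analytic - fd) / max(abs(fd), 1e-8) < 1e-4
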