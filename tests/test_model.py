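"""Architecture contracts: blocks, attention, dilation, full network."""

import numpy as np
import pytest

from funduseg import nn
from funduseg.model import (
    ChannelAttention,
    ConvBlock,
    DilatedBlock,
    DualAttention,
    EADNet,
    IdentityBlock,
    ModelConfig,
    PositionAttention,
    build_model,
    predict,
)
from funduseg.io_masks import FundusImage
from funduseg.nn import Tensor


def small_config(**kw):
    base = dict(input_size=64, base_channels=8, encoder_stages=3,
                attention_stages=(2, 3), dropout_rate=0.0)
    base.update(kw)
    return ModelConfig(**base)


class TestConfig:
    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_size=100, encoder_stages=4)

    def test_attention_on_large_maps_rejected(self):
        with pytest.raises(ValueError, match="affinity"):
            ModelConfig(input_size=512, attention_stages=(1,))

    def test_nonpositive_dilation_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dilation_rates=(0, 2, 5))


class TestResidualBlocks:
    def test_stride_two_halves_spatial_dims(self, rng):
        blk = ConvBlock(8, 16, stride=2, rng=rng)
        out = blk(Tensor(rng.random((1, 8, 64, 64))))
        assert out.shape == (1, 16, 32, 32)

    def test_stride_one_preserves_dims(self, rng):
        blk = ConvBlock(8, 16, stride=1, rng=rng)
        assert blk(Tensor(rng.random((1, 8, 16, 16)))).shape == (1, 16, 16, 16)

    def test_all_kernels_are_3x3(self, rng):
        blk = ConvBlock(8, 16, stride=2, rng=rng)
        for m in blk.modules():
            if isinstance(m, nn.Conv2d):
                assert m.weight.shape[2:] == (3, 3)

    def test_identity_block_preserves_shape(self, rng):
        blk = IdentityBlock(16, rng=rng)
        assert blk(Tensor(rng.random((2, 16, 8, 8)))).shape == (2, 16, 8, 8)

    def test_zeroed_residual_branch_reduces_to_relu(self, rng):
        blk = IdentityBlock(8, rng=rng)
        final_bn = blk.branch.mods[-1]
        final_bn.gamma.data[:] = 0.0
        final_bn.beta.data[:] = 0.0
        x = rng.standard_normal((1, 8, 6, 6))
        out = blk(Tensor(x))
        assert np.allclose(out.data, np.maximum(x, 0.0))

    def test_identity_block_has_fewer_parameters_than_conv_block(self, rng):
        conv = ConvBlock(16, 16, stride=1, rng=rng)
        ident = IdentityBlock(16, rng=rng)
        assert ident.num_parameters() < conv.num_parameters()

    def test_bottleneck_reduces_parameters(self, rng):
        narrow = ConvBlock(16, 32, stride=2, bottleneck_ratio=4, rng=rng)
        wide = ConvBlock(16, 32, stride=2, bottleneck_ratio=1, rng=rng)
        assert narrow.num_parameters() < wide.num_parameters()


class TestAttention:
    def test_position_attention_rows_sum_to_one(self, rng):
        pam = PositionAttention(8, rng=rng)
        attn = pam.attention_weights(Tensor(rng.random((2, 8, 6, 6))))
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_position_attention_zero_scale_is_identity(self, rng):
        pam = PositionAttention(8, rng=rng)
        x = rng.random((1, 8, 5, 5))
        assert np.allclose(pam(Tensor(x)).data, x)

    def test_constant_input_attention_sum_is_constant(self, rng):
        pam = PositionAttention(4, rng=rng)
        pam.gamma.data[:] = 1.0
        x = np.full((1, 4, 4, 4), 0.7)
        out = pam(Tensor(x))
        # weighted sum of identical position features returns the constant,
        # mapped through the value projection, plus the residual
        v = pam.value(Tensor(x)).data
        assert np.allclose(out.data, v + x, atol=1e-10)

    def test_channel_attention_rows_sum_to_one(self, rng):
        cam = ChannelAttention(6)
        attn = cam.attention_weights(Tensor(rng.random((1, 6, 4, 4))))
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_channel_attention_zero_scale_is_identity(self, rng):
        cam = ChannelAttention(6)
        x = rng.random((1, 6, 4, 4))
        assert np.allclose(cam(Tensor(x)).data, x)

    def test_identical_channels_get_identical_attention_rows(self, rng):
        cam = ChannelAttention(4)
        x = rng.random((1, 4, 5, 5))
        x[0, 2] = x[0, 1]  # duplicate channel
        attn = cam.attention_weights(Tensor(x)).data[0]
        assert np.allclose(attn[1], attn[2])

    def test_dual_attention_zero_scales_doubles_input(self, rng):
        dual = DualAttention(8, rng=rng)
        x = rng.random((1, 8, 5, 5))
        out = dual(Tensor(x))
        assert out.shape == x.shape
        assert np.allclose(out.data, 2 * x)


class TestDilatedBlock:
    def test_receptive_field_recurrence(self):
        assert DilatedBlock.receptive_field((1, 2, 5)) == 17
        assert DilatedBlock.receptive_field((1, 1, 1)) == 7

    def test_spatial_dims_preserved(self, rng):
        blk = DilatedBlock(8, (1, 2, 5), rng=rng)
        assert blk(Tensor(rng.random((1, 8, 16, 16)))).shape == (1, 8, 16, 16)

    def test_unit_rates_are_plain_convs(self, rng):
        blk = DilatedBlock(4, (1, 1, 1), rng=rng)
        for m in blk.modules():
            if isinstance(m, nn.Conv2d):
                assert m.dilation == 1 and m.padding == 1

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            DilatedBlock(4, (1, 0, 5), rng=rng)


class TestFullNetwork:
    def test_output_shape_and_range(self, rng):
        net = build_model(small_config(), seed=0)
        out = net(Tensor(rng.random((1, 3, 64, 64))))
        assert out.shape == (1, 4, 64, 64)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_exactly_one_pooling_layer(self):
        net = build_model(small_config(), seed=0)
        pools = [m for m in net.modules() if isinstance(m, nn.MaxPool2d)]
        assert len(pools) == 1

    def test_downsampling_after_pool_uses_stride2_convs(self):
        net = build_model(small_config(), seed=0)
        for stage in net.stages:
            conv_block = stage.mods[0]
            assert isinstance(conv_block, ConvBlock)
            assert conv_block.stride == 2

    def test_encoder_map_sizes_halve_per_stage(self, rng):
        cfg = small_config()
        net = build_model(cfg, seed=0)
        x = Tensor(rng.random((1, 3, 64, 64)))
        h = net.pool(net.stem(x))
        sizes = [h.shape[2]]
        for stage in net.stages:
            h = stage(h)
            sizes.append(h.shape[2])
        assert sizes == [32, 16, 8]

    def test_bottleneck_network_is_smaller(self):
        slim = build_model(small_config(bottleneck_ratio=4), seed=0)
        fat = build_model(small_config(bottleneck_ratio=1), seed=0)
        assert slim.num_parameters() < fat.num_parameters()

    def test_single_training_step_decreases_loss(self, rng):
        from funduseg.training import _bce_dice_loss_graph
        net = build_model(small_config(input_size=32), seed=1)
        x = rng.random((1, 3, 32, 32))
        y = (rng.random((1, 4, 32, 32)) > 0.8).astype(float)
        opt = nn.Adam(net.parameters(), lr=1e-3)
        loss0 = _bce_dice_loss_graph(net(Tensor(x)), y)
        opt.zero_grad()
        loss0.backward()
        opt.step()
        net_eval_loss = _bce_dice_loss_graph(net(Tensor(x)), y)
        assert float(net_eval_loss.data) < float(loss0.data)


class TestPredict:
    def _image(self, rng, size=64):
        return FundusImage(rng.integers(0, 256, (size, size, 3), dtype=np.uint8))

    def test_deterministic_for_fixed_seed(self, rng):
        img = self._image(rng)
        net = build_model(small_config(), seed=5)
        m1, p1 = predict(net, img)
        m2, p2 = predict(net, img)
        for cls in p1:
            assert np.array_equal(p1[cls], p2[cls])

    def test_threshold_bounds(self, rng):
        img = self._image(rng)
        net = build_model(small_config(), seed=5)
        all_on, _ = predict(net, img, threshold=0.0)
        all_off, _ = predict(net, img, threshold=1.0)
        for cls in ("MA", "HE"):
            assert all_on.mask(cls).all()
            assert not all_off.mask(cls).any()

    def test_probabilities_in_unit_interval(self, rng):
        net = build_model(small_config(), seed=5)
        _, probs = predict(net, self._image(rng))
        for p in probs.values():
            assert p.min() >= 0.0 and p.max() <= 1.0

    def test_resolution_mismatch_raises(self, rng):
        net = build_model(small_config(), seed=5)
        with pytest.raises(ValueError, match="input size"):
            predict(net, self._image(rng, size=32))
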