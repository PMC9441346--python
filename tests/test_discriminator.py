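"""Discriminator architecture: dilated inception, CBAM attention, realness head."""

import numpy as np
import pytest

from sadgan import nn
from sadgan.discriminator import (CBAM, ChannelAttention, DilatedInceptionBlock,
                                  DiscConfig, Discriminator, SpatialAttention)
from sadgan.nn import Tensor
from sadgan.nn.tensor import conv2d


def _zero_params(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


class TestDilatedInception:
    def test_rate4_branch_has_9x9_receptive_field(self):
        """Impulse through a dilation-4 3x3 kernel spreads over 9 pixels."""
        x = np.zeros((1, 1, 17, 17), dtype=np.float64)
        x[0, 0, 8, 8] = 1.0
        w = np.ones((1, 1, 3, 3))
        out = conv2d(Tensor(x), Tensor(w), padding=4, dilation=4).data[0, 0]
        rows = np.where(out.any(axis=1))[0]
        cols = np.where(out.any(axis=0))[0]
        assert rows.max() - rows.min() + 1 == 9
        assert cols.max() - cols.min() + 1 == 9

    def test_zero_fuse_reduces_to_activated_identity(self):
        blk = DilatedInceptionBlock(8, (1, 2, 4), np.random.default_rng(0))
        blk.fuse.weight.data = np.zeros_like(blk.fuse.weight.data)
        blk.fuse.bias.data = np.zeros_like(blk.fuse.bias.data)
        x = Tensor(np.random.default_rng(1).standard_normal((1, 8, 12, 12)).astype(np.float32))
        np.testing.assert_allclose(blk(x).data, np.maximum(x.data, 0), atol=1e-6)

    @pytest.mark.parametrize("h,w", [(9, 9), (12, 20)])
    def test_spatial_dims_preserved(self, h, w):
        blk = DilatedInceptionBlock(8, (1, 2, 4), np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).standard_normal((1, 8, h, w)).astype(np.float32))
        assert blk(x).shape == (1, 8, h, w)


class TestChannelAttention:
    def test_zero_mlp_scales_by_half(self):
        ca = ChannelAttention(4, 2, np.random.default_rng(0))
        _zero_params(ca)
        x = Tensor(np.random.default_rng(1).standard_normal((1, 4, 3, 3)))
        np.testing.assert_allclose(ca(x).data, 0.5 * x.data, rtol=1e-6)

    def test_constant_map_gives_sigmoid_of_twice_mlp(self):
        ca = ChannelAttention(2, 2, np.random.default_rng(0))
        v = np.array([0.3, -1.2])
        x = Tensor(np.broadcast_to(v.reshape(1, 2, 1, 1), (1, 2, 4, 4)).copy())
        # avgpool == maxpool == v on a constant map, so gate = sigmoid(2 MLP(v))
        w1, b1 = ca.fc1.weight.data, ca.fc1.bias.data
        w2, b2 = ca.fc2.weight.data, ca.fc2.bias.data
        mlp = np.maximum(v @ w1 + b1, 0) @ w2 + b2
        gate = 1 / (1 + np.exp(-2 * mlp))
        np.testing.assert_allclose(ca(x).data, x.data * gate.reshape(1, 2, 1, 1),
                                   rtol=1e-6)

    def test_hand_set_mlp_oracle(self):
        ca = ChannelAttention(2, 2, np.random.default_rng(0))
        ca.fc1.weight.data = np.array([[1.0], [0.5]])
        ca.fc1.bias.data = np.array([0.0])
        ca.fc2.weight.data = np.array([[0.3, -0.2]])
        ca.fc2.bias.data = np.array([0.1, 0.0])
        x = np.arange(8, dtype=np.float64).reshape(1, 2, 2, 2)

        def mlp(z):
            h = np.maximum(z @ ca.fc1.weight.data + ca.fc1.bias.data, 0)
            return h @ ca.fc2.weight.data + ca.fc2.bias.data

        avg = x.mean(axis=(2, 3)).reshape(2)
        mx = x.max(axis=(2, 3)).reshape(2)
        gate = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
        np.testing.assert_allclose(ca(Tensor(x)).data,
                                   x * gate.reshape(1, 2, 1, 1), rtol=1e-6)

    def test_reduction_must_divide_channels(self):
        with pytest.raises(ValueError, match="divide"):
            ChannelAttention(6, 4, np.random.default_rng(0))


class TestSpatialAttention:
    def test_zero_conv_scales_by_half(self):
        sa = SpatialAttention(7, np.random.default_rng(0))
        _zero_params(sa)
        x = Tensor(np.random.default_rng(1).standard_normal((1, 3, 8, 8)))
        np.testing.assert_allclose(sa(x).data, 0.5 * x.data, rtol=1e-6)

    def test_weight_map_strictly_inside_unit_interval(self):
        sa = SpatialAttention(3, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).standard_normal((1, 5, 6, 6)))
        w = sa.weight_map(x).data
        assert np.all((w > 0) & (w < 1))

    def test_single_channel_hand_conv_oracle(self):
        """C=1: mean and max planes both equal the input; conv by hand."""
        sa = SpatialAttention(3, np.random.default_rng(0))
        k = np.array([[[[0.1, 0.0, -0.2], [0.3, 0.5, 0.0], [0.0, -0.1, 0.2]],
                       [[0.2, 0.1, 0.0], [-0.3, 0.4, 0.1], [0.0, 0.0, -0.1]]]])
        sa.conv.weight.data = k
        sa.conv.bias.data = np.array([0.05])
        x = np.random.default_rng(2).standard_normal((1, 1, 3, 3))

        stacked = np.concatenate([x, x], axis=1)    # mean plane == max plane
        padded = np.pad(stacked, ((0, 0), (0, 0), (1, 1), (1, 1)))
        expected_logit = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                expected_logit[i, j] = np.sum(padded[0, :, i:i + 3, j:j + 3] * k[0]) + 0.05
        gate = 1 / (1 + np.exp(-expected_logit))
        np.testing.assert_allclose(sa(Tensor(x)).data, x * gate, rtol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SpatialAttention(4, np.random.default_rng(0))


class TestCBAM:
    def test_zeroed_attention_scales_by_quarter(self):
        cbam = CBAM(4, 2, 3, np.random.default_rng(0))
        _zero_params(cbam)
        x = Tensor(np.random.default_rng(1).standard_normal((1, 4, 6, 6)))
        np.testing.assert_allclose(cbam(x).data, 0.25 * x.data, rtol=1e-6)

    def test_equals_channel_then_spatial_composition(self):
        cbam = CBAM(4, 2, 3, np.random.default_rng(5))
        x = Tensor(np.random.default_rng(1).standard_normal((1, 4, 8, 8)))
        manual = cbam.spatial(cbam.channel(x))
        np.testing.assert_allclose(cbam(x).data, manual.data, rtol=1e-6)

    def test_shape_preserved(self):
        cbam = CBAM(8, 2, 7, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).standard_normal((1, 8, 8, 8)))
        assert cbam(x).shape == x.shape


class TestDiscriminatorForward:
    def test_score_is_probability(self):
        d = Discriminator(DiscConfig(seed=0))
        p = d.score(np.random.default_rng(0).random((64, 64)))
        assert 0.0 <= p <= 1.0

    def test_softmax_head_complementarity(self):
        d = Discriminator(DiscConfig(seed=0))
        feats = d.features(Tensor(np.random.default_rng(1)
                                  .random((1, 1, 64, 64), dtype=np.float32)))
        z = nn.global_avg_pool(feats)
        probs = nn.softmax(d.head(z), axis=1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_spatial_size_before_global_pool(self):
        d = Discriminator(DiscConfig(seed=0, stages=4))
        feats = d.features(Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        assert feats.shape[2:] == (4, 4)

    def test_indivisible_input_rejected(self):
        d = Discriminator(DiscConfig(seed=0))
        with pytest.raises(ValueError, match="divisible"):
            d(Tensor(np.zeros((1, 1, 50, 64), dtype=np.float32)))

    def test_permutation_of_pixels_changes_score(self, phantom_64):
        d = Discriminator(DiscConfig(seed=3))
        mask = phantom_64.vessel_mask.astype(np.float64)
        p_structured = d.score(mask)
        shuffled = mask.ravel().copy()
        np.random.default_rng(0).shuffle(shuffled)
        p_shuffled = d.score(shuffled.reshape(mask.shape))
        assert abs(p_structured - p_shuffled) > 0

    def test_gradient_reaches_first_conv_block(self):
        d = Discriminator(DiscConfig(seed=0, stages=2, base_channels=8))
        x = Tensor(np.random.default_rng(0).random((1, 1, 16, 16), dtype=np.float32))
        d(x).sum().backward()
        stem_conv = d.stem.body[0]
        assert stem_conv.weight.grad is not None
        assert np.abs(stem_conv.weight.grad).sum() > 0
        missing = [n for n, p in d.named_parameters() if p.grad is None]
        assert missing == []

    def test_spatial_head_returns_grid(self):
        d = Discriminator(DiscConfig(seed=0, stages=3, base_channels=8,
                                     spatial_head=True))
        out = d(Tensor(np.random.default_rng(0).random((1, 1, 32, 32),
                                                       dtype=np.float32)))
        assert out.shape == (1, 4, 4)
        assert np.all((out.data >= 0) & (out.data <= 1))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        DiscConfig(dilation_rates=(1, 2, 3)).validate()
    with pytest.raises(ValueError):
        DiscConfig(spatial_kernel=4).validate()
    with pytest.raises(ValueError):
        DiscConfig(base_channels=12, attn_reduction=64).validate()
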