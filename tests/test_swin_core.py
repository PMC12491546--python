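"""Window partitioning, windowed attention and the transformer block."""

import numpy as np
import pytest

from scalefusionnet import nn
from scalefusionnet.nn import Tensor
from scalefusionnet.swin_core import (
    PatchEmbed,
    PatchMerging,
    SwinBlock,
    WindowAttention,
    WindowConfig,
    window_partition,
    window_reverse,
)

# the four pyramid resolutions of a 256x256 input
PYRAMID = [(96, 64, 64), (192, 32, 32), (384, 16, 16), (768, 8, 8)]


class TestWindowing:
    def test_window_count_and_shape(self, rng):
        x = Tensor(rng.standard_normal((1, 5, 8, 8)).astype(np.float32))
        wins, _ = window_partition(x, 4)
        assert wins.shape == (4, 16, 5)

    @pytest.mark.parametrize("shape,w", [((2, 3, 8, 8), 4), ((1, 2, 6, 6), 4),
                                         ((1, 4, 10, 6), 8)])
    def test_roundtrip_identity(self, rng, shape, w):
        x = rng.standard_normal(shape).astype(np.float32)
        wins, meta = window_partition(Tensor(x), w)
        back = window_reverse(wins, meta)
        assert np.array_equal(back.data, x)

    def test_padded_partition_matches_loop_reference(self, rng):
        """6x6 map, window 4: padded to 8x8 -> 4 windows; compare against
        an explicit python-loop partition of the padded array."""
        x = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
        wins, meta = window_partition(Tensor(x), 4)
        assert wins.shape == (4, 16, 3)
        padded = np.zeros((1, 3, 8, 8), np.float32)
        padded[:, :, 1:7, 1:7] = x  # symmetric: pad 1 on each side
        ref = np.empty((4, 16, 3), np.float32)
        k = 0
        for wi in range(2):
            for wj in range(2):
                block = padded[0, :, 4 * wi:4 * wi + 4, 4 * wj:4 * wj + 4]
                ref[k] = block.transpose(1, 2, 0).reshape(16, 3)
                k += 1
        assert np.array_equal(wins.data, ref)

    def test_invalid_window_size(self):
        with pytest.raises(ValueError, match="window_size"):
            window_partition(Tensor(np.zeros((1, 1, 4, 4), np.float32)), 0)


class TestWindowAttention:
    def test_rows_sum_to_one(self, rng):
        attn = WindowAttention(12, 3, 4, rng=rng)
        tokens = Tensor(rng.standard_normal((5, 16, 12)).astype(np.float32))
        out, weights = attn(tokens, return_attn=True)
        assert out.shape == tokens.shape
        assert np.all(weights.data >= 0)
        assert np.abs(weights.data.sum(-1) - 1.0).max() < 1e-6

    def test_single_token_weight_is_one(self, rng):
        attn = WindowAttention(8, 2, 1, rng=rng)
        tokens = Tensor(rng.standard_normal((3, 1, 8)).astype(np.float32))
        out, weights = attn(tokens, return_attn=True)
        assert np.allclose(weights.data, 1.0)
        # output equals value projection of the input, passed through proj
        v = tokens.data @ attn.qkv.weight.data[:, 16:] + attn.qkv.bias.data[16:]
        ref = v @ attn.proj.weight.data + attn.proj.bias.data
        assert np.abs(out.data - ref).max() < 1e-5

    def test_two_token_hand_computation(self):
        """Scalar-channel window of two tokens against softmax(QK^T/sqrt(d))V
        computed by hand."""
        attn = WindowAttention(1, 1, 2, rng=np.random.default_rng(0))
        # force identity projections and no bias so Q=K=V=input
        attn.qkv.weight.data = np.tile(np.eye(1, dtype=np.float32), (1, 3))
        attn.qkv.bias.data[:] = 0
        attn.proj.weight.data = np.eye(1, dtype=np.float32)
        attn.proj.bias.data[:] = 0
        attn.rel_bias.data[:] = 0
        x = np.array([[[1.0], [2.0]]], dtype=np.float32)
        out = attn(Tensor(x))
        s = np.array([[1.0, 2.0], [2.0, 4.0]])  # q_i * k_j / sqrt(1)
        w = np.exp(s) / np.exp(s).sum(-1, keepdims=True)
        ref = w @ np.array([1.0, 2.0])
        assert np.abs(out.data[0, :, 0] - ref).max() < 1e-5

    def test_head_divisibility_error(self):
        with pytest.raises(ValueError, match="divisible"):
            WindowAttention(10, 3, 4)
        with pytest.raises(ValueError, match="divisible"):
            WindowConfig(window_size=4, num_heads=3, embed_dim=10)


class TestSwinBlock:
    @pytest.mark.parametrize("c,h,w", PYRAMID)
    def test_shape_preserved_at_pyramid_resolutions(self, rng, c, h, w):
        heads = {96: 3, 192: 6, 384: 12, 768: 24}[c]
        block = SwinBlock(WindowConfig(8, heads, c, shift=0), rng=rng)
        x = Tensor(rng.standard_normal((1, c, h, w)).astype(np.float32) * 0.1)
        y = block(x)
        assert y.shape == (1, c, h, w)
        assert np.isfinite(y.data).all()

    def test_zeroed_projections_make_identity(self, rng):
        block = SwinBlock(WindowConfig(4, 2, 8, shift=0), rng=rng)
        block.attn.proj.weight.data[:] = 0
        block.attn.proj.bias.data[:] = 0
        block.mlp_fc2.weight.data[:] = 0
        block.mlp_fc2.bias.data[:] = 0
        x = rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
        y = block(Tensor(x))
        assert np.abs(y.data - x).max() < 1e-6

    def test_shifted_block_differs_but_preserves_shape(self, rng):
        x = Tensor(rng.standard_normal((1, 8, 16, 16)).astype(np.float32))
        plain = SwinBlock(WindowConfig(4, 2, 8, 0), rng=np.random.default_rng(3))
        shifted = SwinBlock(WindowConfig(4, 2, 8, 2), rng=np.random.default_rng(3))
        assert plain(x).shape == shifted(x).shape == (1, 8, 16, 16)
        assert not np.allclose(plain(x).data, shifted(x).data)

    def test_batch_permutation_consistency(self, rng):
        block = SwinBlock(WindowConfig(4, 2, 8, 2), rng=rng)
        x = rng.standard_normal((3, 8, 8, 8)).astype(np.float32)
        y = block(Tensor(x)).data
        perm = [2, 0, 1]
        y_perm = block(Tensor(x[perm])).data
        assert np.abs(y_perm - y[perm]).max() < 1e-6


class TestPatchOps:
    def test_patch_embed_pyramid_entry(self, rng):
        pe = PatchEmbed(96, rng=rng)
        out = pe(Tensor(rng.standard_normal((1, 3, 256, 256)).astype(np.float32)))
        assert out.shape == (1, 96, 64, 64)

    def test_patch_embed_small_and_batch(self, rng):
        pe = PatchEmbed(8, rng=rng)
        out = pe(Tensor(rng.standard_normal((2, 3, 32, 32)).astype(np.float32)))
        assert out.shape == (2, 8, 8, 8)

    def test_patch_embed_constant_input_finite(self, rng):
        pe = PatchEmbed(16, rng=rng)
        out = pe(Tensor(np.full((1, 3, 32, 32), 0.5, np.float32)))
        assert np.isfinite(out.data).all()

    def test_patch_embed_divisibility_error(self, rng):
        pe = PatchEmbed(8, rng=rng)
        with pytest.raises(ValueError, match="divisible"):
            pe(Tensor(np.zeros((1, 3, 30, 30), np.float32)))

    @pytest.mark.parametrize("c,h,w,oc,oh,ow", [
        (96, 64, 64, 192, 32, 32),
        (384, 16, 16, 768, 8, 8),
    ])
    def test_patch_merging_shapes(self, rng, c, h, w, oc, oh, ow):
        pm = PatchMerging(c, rng=rng)
        out = pm(Tensor(rng.standard_normal((2, c, h, w)).astype(np.float32)))
        assert out.shape == (2, oc, oh, ow)

    def test_patch_merging_odd_dims_error(self, rng):
        pm = PatchMerging(4, rng=rng)
        with pytest.raises(ValueError, match="even"):
            pm(Tensor(np.zeros((1, 4, 5, 6), np.float32)))
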