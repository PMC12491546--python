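"""Adaptive fusion block: level policies, deformable convolution oracle,
three-way fusion."""

import numpy as np
import pytest
from scipy import signal

from scalefusionnet.afb import (
    Afb,
    AfbLevelPolicy,
    DeformBranch,
    DeformConv2d,
    SwinBranch,
)
from scalefusionnet.nn import Tensor, no_grad


class TestLevelPolicy:
    @pytest.mark.parametrize("level,stages,reduce", [
        (0, 2, False), (1, 3, False), (2, 4, True), (3, 0, False),
    ])
    def test_piecewise_rule(self, level, stages, reduce):
        p = AfbLevelPolicy.for_level(level)
        assert (p.swin_stages_used, p.reduce_embed) == (stages, reduce)

    def test_cumulative_depths(self):
        assert [AfbLevelPolicy.for_level(i).depth for i in range(4)] == \
            [4, 10, 12, 0]

    def test_invalid_level(self):
        with pytest.raises(ValueError, match="level"):
            AfbLevelPolicy.for_level(5)


class TestSwinBranch:
    def test_level3_is_convolution_only(self, rng):
        branch = SwinBranch(16, AfbLevelPolicy.for_level(3), 16, rng=rng)
        assert not hasattr(branch, "blocks")  # no attention parameters at all
        x = Tensor(rng.standard_normal((1, 16, 8, 8)).astype(np.float32))
        assert branch(x).shape == (1, 16, 8, 8)

    @pytest.mark.parametrize("level,hw", [(0, 16), (1, 8), (2, 4)])
    def test_shape_contract(self, rng, level, hw):
        branch = SwinBranch(8, AfbLevelPolicy.for_level(level), 8,
                            window_size=4, rng=rng)
        x = Tensor(rng.standard_normal((2, 8, hw, hw)).astype(np.float32))
        assert branch(x).shape == (2, 8, hw, hw)

    def test_reduced_level2_smaller_than_level1_at_same_width(self):
        """The level-2 policy (4 stages, halved embedding) instantiates
        fewer branch parameters than level 1 (3 stages, full width)."""
        mk = lambda lvl: SwinBranch(
            32, AfbLevelPolicy.for_level(lvl), 32,
            rng=np.random.default_rng(0)
        )
        p1 = sum(p.size for p in mk(1).parameters())
        p2 = sum(p.size for p in mk(2).parameters())
        assert mk(2).internal_width < mk(1).internal_width
        assert p2 < p1


class TestDeformConv:
    def test_zero_offset_equals_standard_conv(self, rng):
        """With zero offsets the deformable conv is an exact standard 3x3
        convolution (zero padding)."""
        dc = DeformConv2d(3, 4, rng=rng)
        x = rng.standard_normal((2, 3, 10, 10)).astype(np.float32)
        off = np.zeros((2, 18, 10, 10), np.float32)
        with no_grad():
            out = dc(Tensor(x), Tensor(off))
        for b in range(2):
            for o in range(4):
                ref = sum(
                    signal.correlate2d(x[b, c], dc.weight.data[o, c],
                                       mode="same")
                    for c in range(3)
                ) + dc.bias.data[o]
                assert np.abs(out.data[b, o] - ref).max() < 1e-5

    def test_constant_field_averaging_kernel(self, rng):
        dc = DeformConv2d(1, 1, rng=rng)
        dc.weight.data[:] = 1.0 / 9.0
        dc.bias.data[:] = 0.0
        x = np.full((1, 1, 7, 7), 2.0, np.float32)
        off = np.zeros((1, 18, 7, 7), np.float32)
        with no_grad():
            out = dc(Tensor(x), Tensor(off))
        assert np.abs(out.data[0, 0, 1:-1, 1:-1] - 2.0).max() < 1e-6

    def test_integer_offset_shifts_sampling(self, rng):
        """Offset (+1, 0) on every tap equals the standard conv of the
        input shifted by one row."""
        dc = DeformConv2d(1, 1, rng=rng)
        dc.bias.data[:] = 0.0
        ramp = np.arange(25, dtype=np.float32).reshape(1, 1, 5, 5)
        off = np.zeros((1, 18, 5, 5), np.float32)
        off[:, 0:9] = 1.0  # +1 row displacement on all taps
        shifted = np.zeros_like(ramp)
        shifted[:, :, :-1] = ramp[:, :, 1:]  # row h samples row h+1
        with no_grad():
            out = dc(Tensor(ramp), Tensor(off))
            ref = dc(Tensor(shifted), Tensor(np.zeros_like(off)))
        # row 0 differs by construction: the shifted input pads with zeros
        # where the offset sampling still reaches real pixels
        assert np.abs(out.data[:, :, 1:] - ref.data[:, :, 1:]).max() < 1e-5

    def test_offset_gradient_flows(self, rng):
        branch = DeformBranch(2, rng=rng)
        # move offsets off the integer lattice so the interp is differentiable
        branch.offset_conv.bias.data[:] = 0.3
        x = Tensor(rng.standard_normal((1, 2, 6, 6)).astype(np.float32),
                   requires_grad=True)
        branch(x).sum().backward()
        assert branch.offset_conv.bias.grad is not None
        assert np.abs(branch.offset_conv.bias.grad).max() > 0

    def test_branch_zero_init_starts_on_regular_grid(self, rng):
        branch = DeformBranch(3, rng=rng)
        x = rng.standard_normal((1, 3, 8, 8)).astype(np.float32)
        with no_grad():
            out = branch(Tensor(x))
            ref = branch.deform(
                Tensor(x), Tensor(np.zeros((1, 18, 8, 8), np.float32))
            )
        assert np.abs(out.data - ref.data).max() < 1e-6


class TestFusion:
    def test_channel_arithmetic(self, rng):
        afb = Afb(8, 1, 8, window_size=4, rng=rng)
        x = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        assert afb(x).shape == (1, 8, 8, 8)
        assert afb.reduce.weight.shape == (8, 24, 1, 1)

    def test_identity_initialized_reduction_passes_input(self, rng):
        afb = Afb(4, 3, 4, rng=rng)
        afb.reduce.weight.data[:] = 0.0
        for c in range(4):
            afb.reduce.weight.data[c, c, 0, 0] = 1.0  # select identity branch
        afb.reduce.bias.data[:] = 0.0
        x = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        zeros = Tensor(np.zeros_like(x))
        with no_grad():
            out = afb.fuse(Tensor(x), zeros, zeros)
        assert np.abs(out.data - x).max() < 1e-6

    def test_output_depends_on_every_branch(self, rng):
        afb = Afb(4, 2, 8, window_size=4, rng=rng)
        x = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        a = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        b = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        c = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32))
        with no_grad():
            base = afb.fuse(x, a, b).data.copy()
            for k in range(3):
                args = [x, a, b]
                args[k] = args[k] + c
                assert not np.allclose(afb.fuse(*args).data, base), k

    def test_shape_mismatch_error(self, rng):
        afb = Afb(4, 3, 4, rng=rng)
        x = Tensor(np.zeros((1, 4, 8, 8), np.float32))
        y = Tensor(np.zeros((1, 4, 4, 4), np.float32))
        with pytest.raises(ValueError, match="shapes"):
            afb.fuse(x, y, x)

    @pytest.mark.parametrize("level,hw", [(0, 16), (1, 8), (2, 8), (3, 4)])
    def test_full_block_shape_at_levels(self, rng, level, hw):
        afb = Afb(6, level, 8, window_size=4, rng=rng)
        x = Tensor(rng.standard_normal((1, 6, hw, hw)).astype(np.float32))
        assert afb(x).shape == (1, 6, hw, hw)
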