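"""Cross-attention skip refinement: routing, fusion, shared spatial attention."""

import numpy as np
import pytest

from scalefusionnet.catm import (
    ROUTINGS,
    Catm,
    CatmConfig,
    SharedSpatialAttention,
    cross_attention,
)
from scalefusionnet.nn import Tensor, no_grad


def make_catm(dim=8, routing="decoder_all", shared=None, use_sa=True, seed=0):
    shared = shared or SharedSpatialAttention(rng=np.random.default_rng(99))
    return Catm(dim, 2, shared,
                CatmConfig(qkv_routing=routing, use_shared_sa=use_sa,
                           window_size=4),
                rng=np.random.default_rng(seed))


@pytest.fixture
def feats(rng):
    skip = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
    dec = Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
    return skip, dec


class TestCrossAttention:
    def test_single_token_returns_value(self, rng):
        q = Tensor(rng.standard_normal((3, 1, 4)).astype(np.float32))
        k = Tensor(rng.standard_normal((3, 1, 4)).astype(np.float32))
        v = Tensor(rng.standard_normal((3, 1, 4)).astype(np.float32))
        out = cross_attention(q, k, v)
        assert np.abs(out.data - v.data).max() < 1e-6

    def test_two_by_two_toy_hand_computed(self):
        """Scalar channels: V' = softmax(QK^T / sqrt(1)) V by brute force."""
        q = np.array([[[1.0], [0.0]]], np.float32)
        k = np.array([[[2.0], [1.0]]], np.float32)
        v = np.array([[[5.0], [7.0]]], np.float32)
        out = cross_attention(Tensor(q), Tensor(k), Tensor(v))
        s = q[0] @ k[0].T  # (2, 2)
        w = np.exp(s) / np.exp(s).sum(-1, keepdims=True)
        ref = w @ v[0]
        assert np.abs(out.data[0] - ref).max() < 1e-6

    def test_rows_normalized(self, rng):
        q = Tensor(rng.standard_normal((2, 6, 4)).astype(np.float32))
        scores = (q @ q.transpose(0, 2, 1)).softmax(axis=-1)
        assert np.abs(scores.data.sum(-1) - 1).max() < 1e-6

    def test_token_mismatch_error(self, rng):
        a = Tensor(rng.standard_normal((1, 4, 4)).astype(np.float32))
        b = Tensor(rng.standard_normal((1, 5, 4)).astype(np.float32))
        with pytest.raises(ValueError, match="mismatch"):
            cross_attention(a, b, b)


class TestRouting:
    @pytest.mark.parametrize("routing", sorted(ROUTINGS))
    def test_perturbations_follow_declared_sources(self, rng, feats, routing):
        """Perturbing an input changes only the Q/K/V tensors that are
        declared to derive from it."""
        skip, dec = feats
        catm = make_catm(routing=routing)
        with no_grad():
            base = [t.data.copy() for t in catm.derive_qkv(dec, skip)]
            skip2 = Tensor(skip.data + rng.standard_normal(skip.shape)
                           .astype(np.float32))
            after = [t.data.copy() for t in catm.derive_qkv(dec, skip2)]
        srcs = ROUTINGS[routing]
        for name, b, a in zip("QKV", base, after):
            changed = not np.allclose(b, a)
            assert changed == (srcs["QKV".index(name)] == "skip"), (
                f"{routing}: {name} sensitivity to skip wrong"
            )

    def test_decoder_all_shapes(self, rng):
        catm = make_catm(dim=8)
        dec = Tensor(rng.standard_normal((1, 8, 8, 8)).astype(np.float32))
        q, k, v = catm.derive_qkv(dec, dec)
        assert q.shape == k.shape == v.shape == (1, 64, 8)

    def test_spatial_mismatch_error(self, rng, feats):
        skip, _ = feats
        catm = make_catm()
        small = Tensor(np.zeros((2, 8, 4, 4), np.float32))
        with pytest.raises(ValueError, match="spatial"):
            catm.derive_qkv(small, skip)

    def test_unknown_routing_rejected(self):
        with pytest.raises(ValueError, match="routing"):
            CatmConfig(qkv_routing="nonsense")


class TestCaf:
    def test_output_shape_matches_skip(self, rng, feats):
        skip, dec = feats
        catm = make_catm()
        assert catm.caf(dec, skip).shape == skip.shape

    def test_gradient_reaches_both_inputs(self, rng):
        catm = make_catm(dim=4)
        v = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32),
                   requires_grad=True)
        s = Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32),
                   requires_grad=True)
        catm.caf(v, s).sum().backward()
        assert v.grad is not None and np.abs(v.grad).max() > 0
        assert s.grad is not None and np.abs(s.grad).max() > 0

    def test_caf_gradient_matches_numeric(self, rng, numgrad):
        catm = make_catm(dim=2)
        s0 = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
        v0 = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)

        def f(sv):
            return (catm.caf(Tensor(v0), Tensor(sv)) ** 2).sum().item()

        s = Tensor(s0.copy(), requires_grad=True)
        (catm.caf(Tensor(v0), s) ** 2).sum().backward()
        assert np.abs(s.grad - numgrad(f, s0.copy())).max() < 5e-2


class TestSharedSA:
    def test_attention_map_in_open_interval(self, rng, feats):
        skip, _ = feats
        catm = make_catm()
        with no_grad():
            a, x_out = catm.shared_spatial_attention(skip)
        assert a.shape == (2, 1, 8, 8)
        assert np.all((a.data > 0) & (a.data < 1))
        nz = skip.data != 0
        assert np.all(np.abs(x_out.data[nz]) < np.abs(skip.data[nz]))

    def test_parameter_sharing_across_levels(self):
        """Four CATM levels add exactly one shared 3->1 conv parameter set;
        only the per-level C->1 projections (and level blocks) multiply."""
        shared = SharedSpatialAttention(rng=np.random.default_rng(0))
        shared_count = sum(p.size for p in shared.parameters())
        assert shared_count == 3 + 1  # 3->1 kernel + bias

        dims = [8, 12, 16, 24]
        catms = [make_catm(dim=d, shared=shared, seed=d) for d in dims]

        def total(mods):
            seen, tot = set(), 0
            for m in mods:
                for _, p in m.named_parameters(_seen=seen):
                    tot += p.size
            return tot

        all_four = total(catms)
        # counting levels separately double-counts the shared conv 3 times
        separate = sum(total([c]) for c in catms)
        assert separate - all_four == 3 * shared_count

    def test_disabled_shared_sa_returns_refined_skip_exactly(self, feats):
        """With SharedSA off, X_CATM == X'_Skip bit-for-bit."""
        skip, dec = feats
        off = make_catm(use_sa=False, seed=5)
        with no_grad():
            assert np.array_equal(off(skip, dec).data,
                                  off.refine(skip, dec).data)

    def test_enabled_shared_sa_is_elementwise_gating(self, feats):
        skip, dec = feats
        on = make_catm(use_sa=True, seed=5)
        with no_grad():
            x_ref = on.refine(skip, dec)
            a, gated = on.shared_spatial_attention(x_ref)
            full = on(skip, dec)
        assert np.abs(full.data - gated.data).max() < 1e-6
        assert np.abs(full.data - x_ref.data * a.data).max() < 1e-6

    def test_full_forward_shape_and_determinism(self, rng, feats):
        skip, dec = feats
        catm = make_catm()
        with no_grad():
            a = catm(skip, dec).data.copy()
            b = catm(skip, dec).data.copy()
        assert a.shape == skip.data.shape
        assert np.array_equal(a, b)
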