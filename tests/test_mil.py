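"""Dual-attention MIL: Nystrom oracle equivalence, PPEG, cross-attention."""

import numpy as np
import pytest

from dualmil import mil, nn
from dualmil.mil import (CrossAttention, DualAttentionMIL, MILConfig, PPEG,
                         dense_attention, nystrom_attention, square_pad)


def _t(arr):
    return nn.Tensor(np.asarray(arr, dtype=np.float32))


class TestNystromAttention:
    def test_single_token_returns_value(self, rng):
        q = k = _t(rng.standard_normal((1, 4)))
        v = _t(rng.standard_normal((1, 4)))
        out = nystrom_attention(q, k, v, landmarks=4)
        assert np.allclose(out.data, v.data, atol=1e-6)

    def test_exact_regime_matches_dense(self, rng):
        for _ in range(3):
            q, k, v = (rng.standard_normal((8, 4)).astype(np.float32)
                       for _ in range(3))
            out = nystrom_attention(_t(q), _t(k), _t(v), landmarks=8)
            assert np.abs(out.data - dense_attention(q, k, v)).max() < 1e-3

    def test_error_decreases_with_landmarks(self):
        """Mean max-abs error vs the dense oracle shrinks as m grows."""
        errs = {}
        for m in (2, 8, 32):
            per_seed = []
            for s in range(20):
                r = np.random.default_rng(s)
                q, k, v = (r.standard_normal((64, 16)).astype(np.float32)
                           for _ in range(3))
                out = nystrom_attention(_t(q), _t(k), _t(v), m)
                per_seed.append(np.abs(out.data - dense_attention(q, k, v)).max())
            errs[m] = np.mean(per_seed)
        assert errs[2] > errs[8] > errs[32]

    def test_invalid_landmarks(self, rng):
        q = _t(rng.standard_normal((4, 2)))
        with pytest.raises(ValueError):
            nystrom_attention(q, q, q, landmarks=0)

    def test_differentiable(self, rng):
        q = nn.Tensor(rng.standard_normal((12, 4)).astype(np.float32),
                      requires_grad=True)
        out = nystrom_attention(q, q, q, landmarks=4)
        (out * out).sum().backward()
        assert q.grad is not None and np.isfinite(q.grad).all()


class TestSquarePad:
    @pytest.mark.parametrize("n,m,side", [(64, 64, 8), (5, 9, 3), (1, 1, 1)])
    def test_padded_sizes(self, n, m, side, rng):
        feats = _t(rng.standard_normal((n, 4)))
        padded, grid, n_real = square_pad(feats)
        assert padded.shape == (m, 4)
        assert grid == side
        assert n_real == n

    def test_padding_repeats_leading_tokens(self, rng):
        feats = rng.standard_normal((5, 3)).astype(np.float32)
        padded, _, _ = square_pad(_t(feats))
        assert np.array_equal(padded.data[5:], feats[:4])


class TestPPEG:
    def test_zero_convs_identity(self, rng):
        ppeg = PPEG(4, np.random.default_rng(0))
        for c in ppeg.convs:
            c.weight.data[:] = 0.0
        seq = _t(rng.standard_normal((10, 4)))     # 1 class + 9 grid
        out = ppeg(seq, grid_side=3)
        assert np.allclose(out.data, seq.data, atol=1e-7)

    def test_class_token_passthrough(self, rng):
        ppeg = PPEG(4, np.random.default_rng(3))
        seq = _t(rng.standard_normal((10, 4)))
        out = ppeg(seq, grid_side=3)
        assert np.array_equal(out.data[0], seq.data[0])

    def test_single_token_neighborhood(self):
        """A 3x3 ones kernel spreads one nonzero token to its 8-neighbours."""
        ppeg = PPEG(1, np.random.default_rng(0))
        ppeg.convs[0].weight.data[:] = 1.0
        ppeg.convs[1].weight.data[:] = 0.0
        ppeg.convs[2].weight.data[:] = 0.0
        tokens = np.zeros((17, 1), dtype=np.float32)   # 1 class + 4x4 grid
        tokens[1 + 5, 0] = 1.0                          # grid position (1, 1)
        out = ppeg(_t(tokens), grid_side=4).data[1:, 0].reshape(4, 4)
        expected = np.zeros((4, 4), dtype=np.float32)
        expected[1, 1] = 1.0                            # residual
        expected[0:3, 0:3] += 1.0                       # 3x3 convolution of ones
        assert np.array_equal(out, expected)

    def test_nonsquare_grid_rejected(self, rng):
        ppeg = PPEG(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            ppeg(_t(rng.standard_normal((7, 4))), grid_side=3)


class TestBranchEncoders:
    def test_identical_instances_uniform_attention(self):
        model = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=0))
        row = np.ones((1, 8), dtype=np.float32)
        feats = _t(np.repeat(row, 9, axis=0))
        _, _, _, attn, _ = model.encode_image_bag(feats)
        assert np.allclose(attn.weights, 1 / 9, atol=1e-6)

    @pytest.mark.parametrize("n", [1, 5, 64])
    def test_bag_vector_shape_any_n(self, n, rng):
        model = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=0))
        vec, *_ = model.encode_image_bag(_t(rng.standard_normal((n, 8))))
        assert vec.shape == (8,)

    def test_attention_weights_distribution(self, rng):
        model = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=1))
        _, _, _, attn, _ = model.encode_image_bag(_t(rng.standard_normal((5, 8))))
        assert attn.weights.min() >= 0
        assert attn.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert len(attn.weights) == 5   # padded positions excluded

    def test_gene_branch_permutation_equivariant(self, rng):
        model = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=2))
        lat = rng.standard_normal((7, 8)).astype(np.float32)
        vec, _, _, attn, _ = model.encode_gene_bag(_t(lat))
        perm = rng.permutation(7)
        vec_p, _, _, attn_p, _ = model.encode_gene_bag(_t(lat[perm]))
        assert np.allclose(vec.data, vec_p.data, atol=1e-5)
        assert np.allclose(attn.weights[perm], attn_p.weights, atol=1e-5)

    def test_image_branch_not_permutation_invariant(self, rng):
        """Once PPEG weights move off zero (as in training), the grid
        layout makes the image branch order-sensitive."""
        model = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=2))
        for c in model.ppeg.convs:
            c.weight.data = rng.standard_normal(c.weight.shape).astype(
                np.float32) * 0.3
        feats = rng.standard_normal((9, 8)).astype(np.float32)
        vec, *_ = model.encode_image_bag(_t(feats))
        perm = np.roll(np.arange(9), 4)
        vec_p, *_ = model.encode_image_bag(_t(feats[perm]))
        assert not np.allclose(vec.data, vec_p.data, atol=1e-5)

    def test_single_gene_set_full_weight(self, rng):
        model = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=0))
        _, _, _, attn, _ = model.encode_gene_bag(_t(rng.standard_normal((1, 8))))
        assert attn.weights.tolist() == [1.0]

    def test_identical_gene_rows_uniform(self):
        model = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=0))
        lat = np.tile(np.arange(8, dtype=np.float32), (6, 1))
        _, _, _, attn, _ = model.encode_gene_bag(_t(lat))
        assert np.allclose(attn.weights, 1 / 6, atol=1e-6)


class TestCrossAttention:
    def test_single_key_full_weight(self, rng):
        ca = CrossAttention(8, 2, np.random.default_rng(0))
        vec, w = ca(_t(rng.standard_normal(8)), _t(rng.standard_normal((1, 8))))
        assert w.tolist() == pytest.approx([1.0])
        assert vec.shape == (8,)

    def test_identical_keys_uniform(self, rng):
        ca = CrossAttention(8, 2, np.random.default_rng(1))
        keys = np.tile(rng.standard_normal(8).astype(np.float32), (5, 1))
        _, w = ca(_t(rng.standard_normal(8)), _t(keys))
        assert np.allclose(w, 0.2, atol=1e-6)

    def test_matches_dense_single_query_oracle(self, rng):
        dim, heads = 8, 2
        ca = CrossAttention(dim, heads, np.random.default_rng(2))
        qv = rng.standard_normal(dim).astype(np.float32)
        keys = rng.standard_normal((6, dim)).astype(np.float32)
        _, w = ca(_t(qv), _t(keys))
        # oracle: head-averaged softmax over projected keys
        dh = dim // heads
        q = (qv @ ca.wq.weight.data).reshape(heads, 1, dh)
        k = (keys @ ca.wk.weight.data).reshape(6, heads, dh).transpose(1, 0, 2)
        scores = np.einsum("hqd,hnd->hqn", q, k) / np.sqrt(dh)
        e = np.exp(scores - scores.max(-1, keepdims=True))
        expected = (e / e.sum(-1, keepdims=True))[:, 0].mean(axis=0)
        assert np.allclose(w, expected, atol=1e-5)

    def test_empty_keys_rejected(self, rng):
        ca = CrossAttention(8, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            ca(_t(rng.standard_normal(8)), _t(np.zeros((0, 8))))


class TestFusionAndClassifier:
    def test_zero_classifier_ties_logits(self, rng):
        model = DualAttentionMIL(MILConfig(dim=4, heads=2, seed=0))
        model.classifier.weight.data[:] = 0.0
        model.classifier.bias.data[:] = 0.0
        vs = [_t(rng.standard_normal(4)) for _ in range(4)]
        logits = model.fuse_and_classify(*vs)
        assert logits.data[0, 0] == logits.data[0, 1]

    def test_hand_set_linear_head(self):
        model = DualAttentionMIL(MILConfig(dim=2, heads=2, seed=0))
        w = np.arange(16, dtype=np.float32).reshape(8, 2)
        model.classifier.weight.data = w
        model.classifier.bias.data[:] = 0.0
        vs = [np.array([1.0, 2.0]), np.array([3.0, 4.0]),
              np.array([5.0, 6.0]), np.array([7.0, 8.0])]
        logits = model.fuse_and_classify(*[_t(v) for v in vs])
        expected = np.concatenate(vs) @ w
        assert np.allclose(logits.data[0], expected, atol=1e-5)

    def test_length_mismatch_rejected(self, rng):
        model = DualAttentionMIL(MILConfig(dim=4, heads=2, seed=0))
        good = _t(rng.standard_normal(4))
        bad = _t(rng.standard_normal(3))
        with pytest.raises(ValueError):
            model.fuse_and_classify(good, good, good, bad)

    def test_forward_produces_four_vectors_and_records(self, rng):
        model = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=0))
        feats = _t(rng.standard_normal((9, 8)))
        lat = _t(rng.standard_normal((5, 8)))
        logits, out = model.forward_patient(feats, lat)
        for v in (out.vec_self_image, out.vec_self_gene,
                  out.vec_cross_image, out.vec_cross_gene):
            assert v.shape == (8,)
        assert logits.shape == (1, 2)
        assert sorted(r.mechanism for r in out.attention) == sorted(mil.MECHANISMS)
        for r in out.attention:
            assert r.weights.min() >= 0
            assert r.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_self_only_ablation_halves_classifier_input(self, rng):
        fused = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=0))
        ablated = DualAttentionMIL(MILConfig(dim=8, heads=2, seed=0,
                                             self_only=True))
        assert fused.classifier.weight.shape == (32, 2)
        assert ablated.classifier.weight.shape == (16, 2)
        feats = _t(rng.standard_normal((4, 8)))
        lat = _t(rng.standard_normal((3, 8)))
        logits, out = ablated.forward_patient(feats, lat)
        assert logits.shape == (1, 2)
        assert len(out.attention) == 2
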