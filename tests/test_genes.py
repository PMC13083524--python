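"""TPM normalization, gene-set tensors and the masked-MSE autoencoder."""

import numpy as np
import pandas as pd
import pytest

from dualmil import genes, nn
from dualmil.genes import (GeneSetDefinition, GeneSetTensor,
                           build_geneset_tensor, encode_genesets, masked_mse,
                           select_significant, tpm_log, train_autoencoder)


def _sets(*sizes, padj=0.001):
    out = []
    g = 0
    for i, n in enumerate(sizes):
        members = tuple(f"g{j}" for j in range(g, g + n))
        g += n
        out.append(GeneSetDefinition(f"S{i}", "synthetic", members, padj))
    return out


class TestSelectSignificant:
    def test_strictly_below_alpha(self):
        sets = [GeneSetDefinition(f"S{i}", "GO", ("a",), p)
                for i, p in enumerate([0.005, 0.01, 0.02])]
        kept = select_significant(sets, alpha=0.01)
        assert [s.set_id for s in kept] == ["S0"]

    def test_none_significant(self):
        sets = [GeneSetDefinition("S", "GO", ("a",), 0.5)]
        assert select_significant(sets) == []

    def test_alpha_one_keeps_all(self):
        sets = [GeneSetDefinition(f"S{i}", "GO", ("a",), p)
                for i, p in enumerate([0.3, 0.9])]
        assert select_significant(sets, alpha=1.0) == sets


class TestTpmLog:
    def test_single_gene_forced_to_million(self):
        counts = pd.DataFrame({"P1": [50]}, index=["g1"])
        lengths = pd.Series([1500], index=["g1"])
        out = tpm_log(counts, lengths)
        assert out.loc["g1", "P1"] == pytest.approx(np.log2(1e6 + 1), abs=1e-9)

    def test_two_gene_hand_computation(self):
        counts = pd.DataFrame({"P1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 2000], index=["g1", "g2"])
        out = tpm_log(counts, lengths)
        # rates 10, 5 -> TPM 666666.67 / 333333.33
        assert out.loc["g1", "P1"] == pytest.approx(np.log2(2e6 / 3 + 1), rel=1e-9)
        assert out.loc["g2", "P1"] == pytest.approx(np.log2(1e6 / 3 + 1), rel=1e-9)

    def test_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (30, 5)),
                              index=[f"g{i}" for i in range(30)],
                              columns=[f"P{i}" for i in range(5)])
        lengths = pd.Series(rng.integers(500, 5000, 30), index=counts.index)
        tpm = 2.0 ** tpm_log(counts, lengths) - 1.0
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_column_warns_and_zeroes(self):
        counts = pd.DataFrame({"P1": [5, 5], "P2": [0, 0]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 1000], index=["g1", "g2"])
        with pytest.warns(UserWarning):
            out = tpm_log(counts, lengths)
        assert (out["P2"] == 0).all()


class TestGeneSetTensor:
    def test_shape_and_mask_rowsums(self):
        sets = _sets(3, 5)
        expr = pd.Series(np.arange(8, dtype=float), index=[f"g{i}" for i in range(8)])
        t = build_geneset_tensor(expr, sets)
        assert t.values.shape == (2, 5)
        assert t.mask.sum(axis=1).tolist() == [3.0, 5.0]

    def test_direct_construction(self):
        sets = [GeneSetDefinition("S", "GO", ("g1", "g2"), 0.001),
                GeneSetDefinition("T", "GO", ("a", "b", "c", "d"), 0.001)]
        expr = pd.Series({"g1": 1.5, "g2": 0.5, "a": 1, "b": 1, "c": 1, "d": 1})
        t = build_geneset_tensor(expr, sets)
        assert t.values[0].tolist() == [1.5, 0.5, 0.0, 0.0]
        assert t.mask[0].tolist() == [1, 1, 0, 0]

    def test_full_row_mask(self):
        sets = _sets(4)
        expr = pd.Series(np.ones(4), index=[f"g{i}" for i in range(4)])
        t = build_geneset_tensor(expr, sets)
        assert t.mask[0].all()

    def test_unknown_gene_named_in_error(self):
        sets = [GeneSetDefinition("SX", "GO", ("missing_gene",), 0.001)]
        expr = pd.Series({"g0": 1.0})
        with pytest.raises(KeyError, match="missing_gene.*SX"):
            build_geneset_tensor(expr, sets)


class TestMaskedMse:
    def test_identity_zero(self):
        x = np.arange(6.0).reshape(2, 3)
        assert masked_mse(x, x, np.ones_like(x)) == 0.0

    def test_hand_value(self):
        x = np.array([1.0, 2.0, 7.0])
        assert masked_mse(x, np.zeros(3), np.array([1.0, 1.0, 0.0])) == 2.5

    def test_padding_invariance_exact(self, rng):
        x = rng.normal(size=(4, 6))
        xhat = rng.normal(size=(4, 6))
        mask = (rng.uniform(size=(4, 6)) > 0.4).astype(float)
        mask[0, 0] = 1.0
        base = masked_mse(x, xhat, mask)
        x2 = x.copy()
        x2[mask == 0] += rng.normal(size=(mask == 0).sum()) * 100
        assert masked_mse(x2, xhat, mask) == base

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            masked_mse(np.ones(3), np.ones(3), np.zeros(3))


def _tensor_batch(n_rows=40, p=12, seed=0):
    rng = np.random.default_rng(seed)
    tensors = []
    for i in range(n_rows // 4):
        values = rng.normal(size=(4, p))
        mask = np.zeros((4, p))
        for r in range(4):
            k = rng.integers(4, p + 1)
            mask[r, :k] = 1
        values = values * mask
        tensors.append(GeneSetTensor(f"P{i}", values, mask))
    return tensors


class TestAutoencoder:
    def test_seeded_training_reproducible(self):
        tensors = _tensor_batch()
        _, l1 = train_autoencoder(tensors, latent_dim=4, epochs=5, seed=3)
        _, l2 = train_autoencoder(tensors, latent_dim=4, epochs=5, seed=3)
        assert l1 == l2

    def test_loss_decreases(self):
        tensors = _tensor_batch(n_rows=200, p=16, seed=1)
        _, losses = train_autoencoder(tensors, latent_dim=6, epochs=50, seed=0)
        assert losses[-1] < losses[0]

    def test_padded_perturbation_leaves_trajectory_unchanged(self):
        tensors = _tensor_batch(seed=2)
        model_a, losses_a = train_autoencoder(tensors, 4, epochs=4, seed=5)
        perturbed = []
        rng = np.random.default_rng(9)
        for t in tensors:
            tp = GeneSetTensor(t.patient_id, t.values.copy(), t.mask)
            pad = tp.mask == 0
            tp.values[pad] += rng.normal(size=int(pad.sum())) * 50  # bypass contract
            perturbed.append(tp)
        model_b, losses_b = train_autoencoder(perturbed, 4, epochs=4, seed=5)
        assert losses_a == losses_b
        for pa, pb in zip(model_a.parameters(), model_b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_masked_gradient_exactly_ignores_padding(self):
        """Gradient wrt padded inputs is exactly zero under the masked loss."""
        rng = np.random.default_rng(0)
        p = 8
        values = rng.normal(size=(3, p)).astype(np.float32)
        mask = np.ones((3, p), dtype=np.float32)
        mask[:, 5:] = 0
        values = values * mask
        model = genes.GeneSetAutoencoder(p, 3, seed=0)
        x = nn.Tensor(values, requires_grad=True)
        m = nn.Tensor(mask)
        diff = x - model(x, m)
        loss = (m * diff * diff).sum() / float(mask.sum())
        loss.backward()
        assert np.all(x.grad[:, 5:] == 0.0)
        assert np.any(x.grad[:, :5] != 0.0)

    def test_encode_shapes_and_permutation(self):
        tensors = _tensor_batch()
        model, _ = train_autoencoder(tensors, latent_dim=4, epochs=3, seed=1)
        t = tensors[0]
        lat = encode_genesets(model, t)
        assert lat.features.shape == (4, 4)
        perm = [2, 0, 3, 1]
        t_perm = GeneSetTensor(t.patient_id, t.values[perm], t.mask[perm])
        lat_perm = encode_genesets(model, t_perm)
        assert np.allclose(lat_perm.features, lat.features[perm])

    def test_width_mismatch_rejected(self):
        tensors = _tensor_batch(p=12)
        model, _ = train_autoencoder(tensors, latent_dim=4, epochs=1, seed=0)
        bad = GeneSetTensor("x", np.ones((2, 5)), np.ones((2, 5)))
        with pytest.raises(ValueError):
            encode_genesets(model, bad)

    def test_no_compression_warns(self):
        with pytest.warns(UserWarning):
            genes.GeneSetAutoencoder(4, 8, seed=0)
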