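"""Attention-weight statistics: MWU, BH-FDR, permutation, heatmaps."""

import numpy as np
import pandas as pd
import pytest

from _oracles import exact_mwu_p
from dualmil import analysis, mil, synthetic
from dualmil.analysis import (AttentionTable, fdr_bh, mwu, permutation_check,
                              render_heatmap, significance_table)
from dualmil.tiling import Patch, PatchBag


class TestMWU:
    def test_fully_separated_small_groups(self):
        u, p = mwu([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_identical_groups_no_separation(self):
        _, p = mwu([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_symmetry_under_swap(self, rng):
        a, b = rng.uniform(size=5), rng.uniform(size=7)
        assert mwu(a, b)[1] == pytest.approx(mwu(b, a)[1])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu([], [1.0])

    def test_normal_approximation_close_to_enumeration(self, rng):
        """For groups of 8, the tie-corrected normal p is within 0.02 of
        the exact enumeration over all C(16,8) assignments."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            a = r.uniform(size=8)
            b = r.uniform(size=8) + 0.3
            _, p_approx = mwu(a, b)          # min size >= 8 -> asymptotic
            p_exact = exact_mwu_p(a, b)
            assert abs(p_approx - p_exact) < 0.02


class TestFdrBH:
    def test_hand_computation(self):
        adj = fdr_bh([0.001, 0.02, 0.9])
        assert np.allclose(adj, [0.003, 0.03, 0.9])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.04]).tolist() == [0.04]

    def test_all_equal_stay_equal(self):
        adj = fdr_bh([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_never_below_raw_and_rank_preserving(self, rng):
        p = np.sort(rng.uniform(size=12))
        adj = fdr_bh(p)
        assert (adj >= p - 1e-15).all()
        assert (np.diff(adj) >= -1e-15).all()

    def test_matches_stepup_definition(self, rng):
        p = rng.uniform(size=9)
        order = np.argsort(p)
        m = len(p)
        stepup = p[order] * m / np.arange(1, m + 1)
        stepup = np.minimum.accumulate(stepup[::-1])[::-1].clip(max=1.0)
        expected = np.empty(m)
        expected[order] = stepup
        assert np.allclose(fdr_bh(p), expected)


class TestPermutationCheck:
    def _table(self, col, labels):
        n = len(labels)
        values = np.stack([col, 1.0 - col], axis=1)
        df = pd.DataFrame(values, columns=["SET000", "SET001"],
                          index=[f"p{i}" for i in range(n)])
        lab = pd.Series(labels, index=df.index)
        return AttentionTable(df, lab, "self_gene")

    def test_constant_column_p_one(self):
        table = self._table(np.full(10, 0.5), [0] * 5 + [1] * 5)
        assert permutation_check(table, "SET000", n_perm=200, seed=0) == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        table = self._table(rng.uniform(0.2, 0.8, 12), [0] * 6 + [1] * 6)
        a = permutation_check(table, "SET000", n_perm=199, seed=3)
        b = permutation_check(table, "SET000", n_perm=199, seed=3)
        assert a == b

    def test_strong_separation_minimal_p(self):
        col = np.array([0.9] * 20 + [0.1] * 20)
        table = self._table(col, [1] * 20 + [0] * 20)
        assert permutation_check(table, "SET000", n_perm=999, seed=1) == \
            pytest.approx(1 / 1000)

    def test_reduced_case_matches_exhaustive_probability(self):
        """n=4/4 fully separated: only the two exact groupings reach the
        observed gap, so perm_p estimates (1 + n_perm*2/70) / (n_perm+1)."""
        col = np.array([0.8] * 4 + [0.2] * 4)
        table = self._table(col, [1] * 4 + [0] * 4)
        p = permutation_check(table, "SET000", n_perm=999, seed=0)
        expected = (1 + 999 * (2 / 70)) / 1000
        assert p == pytest.approx(expected, abs=0.02)

    def test_small_n_perm_warns(self):
        table = self._table(np.linspace(0.3, 0.7, 8), [0] * 4 + [1] * 4)
        with pytest.warns(UserWarning):
            permutation_check(table, "SET000", n_perm=50, seed=0)


class TestSignificancePipeline:
    def test_flags_exactly_forced_sets(self):
        """Forced class shifts on k sets are recovered, nothing else."""
        flagged_ok = 0
        for seed in range(3):
            table, shifted = synthetic.make_attention_table(
                n_per_class=40, n_sets=10, shifted_sets=3, seed=seed)
            results = significance_table(table, alpha=0.01, n_perm=199,
                                         seed=seed)
            sig = {r.set_id for r in results if r.significant}
            if sig == set(shifted):
                flagged_ok += 1
            for r in results:
                if r.significant:
                    assert r.perm_p is not None and r.perm_p < 0.05
        assert flagged_ok >= 2   # 3-seed majority under stochastic conditions

    def test_null_cohort_type_one_control(self):
        """Label-independent attention yields <= 2% significant sets."""
        rates = []
        for seed in range(3):
            table, _ = synthetic.make_attention_table(
                n_per_class=40, n_sets=100, shifted_sets=2, effect=0.0,
                seed=100 + seed)
            results = significance_table(table, alpha=0.01,
                                         run_permutation=False)
            rates.append(np.mean([r.significant for r in results]))
        assert np.median(rates) <= 0.02

    def test_fdr_column_dominates_raw(self):
        table, _ = synthetic.make_attention_table(seed=5)
        for r in significance_table(table, run_permutation=False):
            assert r.p_fdr >= r.p_raw - 1e-15


class TestCollectAttention:
    def test_rows_and_columns(self, small_bags, small_latents, small_cohort):
        from dualmil.backbone import tiny_backbone_spec
        from dualmil.train import MultimodalClassifier
        latents, sig = small_latents
        model = MultimodalClassifier(tiny_backbone_spec(16),
                                     mil.MILConfig(dim=16, heads=2, seed=0),
                                     seed=0)
        pids = sorted(small_bags)[:4]
        table = analysis.collect_attention(
            model, small_bags, latents, small_cohort.labels, pids,
            mechanism="self_gene", set_ids=[s.set_id for s in sig])
        assert list(table.values.index) == pids
        assert table.values.shape == (4, len(sig))
        assert np.allclose(table.values.sum(axis=1), 1.0, atol=1e-6)

    def test_pure_function_of_patient(self, small_bags, small_latents,
                                      small_cohort):
        from dualmil.backbone import tiny_backbone_spec
        from dualmil.train import MultimodalClassifier
        latents, sig = small_latents
        model = MultimodalClassifier(tiny_backbone_spec(16),
                                     mil.MILConfig(dim=16, heads=2, seed=0),
                                     seed=0)
        pid = sorted(small_bags)[0]
        t1 = analysis.collect_attention(model, small_bags, latents,
                                        small_cohort.labels, [pid],
                                        set_ids=[s.set_id for s in sig])
        t2 = analysis.collect_attention(model, small_bags, latents,
                                        small_cohort.labels, [pid],
                                        set_ids=[s.set_id for s in sig])
        assert np.array_equal(t1.values.values, t2.values.values)


class TestRenderHeatmap:
    def _bag(self, n, ps=32):
        patches = [Patch("p", i // 2, i % 2, ((i // 2) * ps, (i % 2) * ps),
                         np.zeros((ps, ps, 3), dtype=np.uint8), 1.0)
                   for i in range(n)]
        return PatchBag("p", 0, patches, n)

    def test_uniform_weights_uniform_cells(self):
        bag = self._bag(4)
        rec = mil.AttentionRecord("self_image", np.full(4, 0.25), 2)
        canvas, _ = render_heatmap(bag, rec, (64, 64), 32)
        assert np.all(canvas == 1.0)   # min-max of a constant maps to 1

    def test_one_hot_top_patch(self):
        bag = self._bag(4)
        w = np.array([0.0, 1.0, 0.0, 0.0])
        rec = mil.AttentionRecord("self_image", w / w.sum(), 2)
        canvas, top = render_heatmap(bag, rec, (64, 64), 32)
        assert top == (0, 1)
        assert canvas[0:32, 32:64].max() == 1.0
        assert canvas[0:32, 0:32].max() == 0.0

    def test_cells_equal_scaled_weights(self):
        bag = self._bag(4)
        w = np.array([0.1, 0.2, 0.3, 0.4])
        rec = mil.AttentionRecord("self_image", w, 2)
        canvas, top = render_heatmap(bag, rec, (64, 64), 32)
        scaled = (w - w.min()) / (w.max() - w.min())
        for p, s in zip(bag.patches, scaled):
            y, x = p.pixel_origin
            assert canvas[y, x] == pytest.approx(s)
        assert top == (1, 1)

    def test_length_mismatch_rejected(self):
        bag = self._bag(4)
        rec = mil.AttentionRecord("self_image", np.full(2, 0.5), 2)
        with pytest.raises(ValueError):
            render_heatmap(bag, rec, (64, 64), 32)
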