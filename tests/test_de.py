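"""Simplified NB differential expression: filtering, normalisation, Wald test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wdtrace as w
from wdtrace.de import DEResult

from helpers import stepup_bh


class TestFilterLowExpressed:
    def test_all_zero_gene_removed(self):
        cs = w.make_nb_counts(5, n_per_group=3, seed=0)
        cs.counts[2] = 0
        out = w.filter_low_expressed(cs, min_total=1)
        assert cs.gene_ids[2] not in out.gene_ids
        assert len(out.gene_ids) == 4

    def test_min_total_zero_is_identity(self):
        cs = w.make_nb_counts(6, n_per_group=3, seed=1)
        out = w.filter_low_expressed(cs, min_total=0)
        assert np.array_equal(out.counts, cs.counts)

    def test_row_sum_oracle(self):
        cs = w.make_nb_counts(10, n_per_group=2, base_mean=3, seed=2)
        sums = cs.counts.sum(axis=1)
        out = w.filter_low_expressed(cs, min_total=10)
        assert out.gene_ids == [g for g, s in zip(cs.gene_ids, sums) if s >= 10]

    def test_de_gene_indices_remapped(self):
        cs = w.make_nb_counts(10, n_per_group=3, n_de=3, base_mean=50, seed=3)
        cs.counts[0] = 0  # drop the first gene
        out = w.filter_low_expressed(cs, min_total=1)
        planted_ids = {cs.gene_ids[g] for g in cs.de_genes} - {cs.gene_ids[0]}
        assert {out.gene_ids[g] for g in out.de_genes} == planted_ids

    def test_removing_everything_rejected(self):
        cs = w.make_nb_counts(3, n_per_group=2, base_mean=1, seed=4)
        with pytest.raises(ValueError, match="every gene"):
            w.filter_low_expressed(cs, min_total=10**9)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [5]]), (1, 4))
        assert np.allclose(w.size_factors(counts), 1.0)

    def test_doubled_sample_doubled_factor(self):
        base = np.array([[10.0], [20.0], [5.0], [40.0]])
        counts = np.hstack([base, base, 2 * base])
        f = w.size_factors(counts)
        assert f[2] / f[0] == pytest.approx(2.0)

    def test_matches_median_of_ratios_hand_computation(self, rng):
        counts = rng.integers(1, 200, size=(8, 5)).astype(float)
        geo = np.exp(np.log(counts).mean(axis=1, keepdims=True))
        raw = np.median(counts / geo, axis=0)
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(w.size_factors(counts), expected)

    def test_fallback_to_library_size(self, caplog):
        counts = np.array([[0, 5], [3, 0]])  # no all-positive gene
        with caplog.at_level("WARNING"):
            f = w.size_factors(counts)
        assert "total-count" in caplog.text
        assert f[1] / f[0] == pytest.approx(5 / 3)


class TestNbWaldTest:
    def test_identical_groups_zero_lfc(self):
        cs = w.make_nb_counts(10, n_per_group=4, seed=0)
        counts = np.hstack([cs.counts[:, :4], cs.counts[:, :4]])
        res = w.nb_wald_test(counts, ["A"] * 4 + ["B"] * 4)
        assert np.all(res["log2_fold_change"] == 0)

    def test_all_zero_gene_gets_p_one(self):
        cs = w.make_nb_counts(5, n_per_group=4, seed=1)
        cs.counts[0] = 0
        res = w.nb_wald_test(cs.counts, cs.group_labels, cs.gene_ids)
        assert res.loc[cs.gene_ids[0], "p_value"] == 1.0

    def test_lfc_antisymmetric_under_group_swap(self):
        cs = w.make_nb_counts(50, n_per_group=10, n_de=5, seed=2)
        res_ab = w.nb_wald_test(cs.counts, cs.group_labels, cs.gene_ids)
        swapped = ["B" if g == "A" else "A" for g in cs.group_labels]
        res_ba = w.nb_wald_test(cs.counts, swapped, cs.gene_ids)
        assert np.allclose(
            res_ab["log2_fold_change"], -res_ba["log2_fold_change"]
        )

    def test_null_p_values_approximately_uniform(self):
        from scipy.stats import kstest

        cs = w.make_nb_counts(2000, n_per_group=40, n_de=0, seed=3)
        res = w.nb_wald_test(cs.counts, cs.group_labels, cs.gene_ids)
        stat = kstest(res["p_value"], "uniform").statistic
        assert stat < 0.05

    def test_planted_genes_recovered(self):
        cs = w.make_nb_counts(500, n_per_group=40, n_de=25, lfc=3, seed=4)
        res = w.nb_wald_test(cs.counts, cs.group_labels, cs.gene_ids)
        selected = set(w.select_de_genes(res))
        planted = {cs.gene_ids[g] for g in cs.de_genes}
        null = set(cs.gene_ids) - planted
        assert len(selected & planted) / len(planted) >= 0.9
        assert len(selected & null) / len(null) <= 0.01

    def test_needs_two_groups_with_two_samples(self):
        cs = w.make_nb_counts(5, n_per_group=2, seed=5)
        with pytest.raises(ValueError, match="two groups"):
            w.nb_wald_test(cs.counts, ["A"] * 4)


class TestSelectAndRank:
    @pytest.fixture
    def table(self) -> DEResult:
        return pd.DataFrame(
            {
                "base_mean": [10.0] * 6,
                "log2_fold_change": [3.0, -4.0, 1.0, 2.5, 0.1, -2.5],
                "p_value": [1e-5, 1e-6, 1e-3, 0.009, 0.5, 0.011],
                "p_adjust": [1e-4, 1e-5, 0.02, 0.01, 0.6, 0.03],
            },
            index=pd.Index(["g1", "g2", "g3", "g4", "g5", "g6"], name="gene_id"),
        )

    def test_filter_thresholds_strict(self, table):
        # g4 sits exactly at p_adjust == 0.01 -> excluded; |lfc|>2 required
        assert w.select_de_genes(table) == ["g1", "g2"]

    def test_empty_table_gives_empty_list(self, table):
        assert w.select_de_genes(table.iloc[:0]) == []

    def test_top_k_exceeding_table_returns_all(self, table):
        assert set(w.top_k_genes(table, k=100)) == set(table.index)

    def test_tie_on_padjust_broken_by_abs_lfc(self):
        t = pd.DataFrame(
            {
                "base_mean": [1.0, 1.0],
                "log2_fold_change": [1.0, -3.0],
                "p_value": [0.01, 0.01],
                "p_adjust": [0.02, 0.02],
            },
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        assert w.top_k_genes(t, k=1) == ["b"]

    def test_matches_full_sort_oracle(self, rng):
        n = 200
        t = pd.DataFrame(
            {
                "base_mean": np.ones(n),
                "log2_fold_change": rng.normal(size=n),
                "p_value": rng.uniform(size=n),
                "p_adjust": np.round(rng.uniform(size=n), 2),  # force ties
            },
            index=pd.Index([f"g{i:03d}" for i in range(n)], name="gene_id"),
        )
        expected = sorted(
            t.index,
            key=lambda g: (
                t.loc[g, "p_adjust"],
                -abs(t.loc[g, "log2_fold_change"]),
                g,
            ),
        )[:100]
        assert w.top_k_genes(t, k=100) == expected


class TestBhAdjust:
    def test_single_and_constant_inputs_unchanged(self):
        assert w.bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(w.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_worked_example(self):
        out = w.bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            w.bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        p=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_matches_stepup_oracle_and_order_invariance(self, p):
        ours = w.bh_adjust(p)
        assert np.allclose(ours, stepup_bh(p))
        perm = np.random.RandomState(0).permutation(len(p))
        assert np.allclose(w.bh_adjust(np.asarray(p)[perm]), ours[perm])
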