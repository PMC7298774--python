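from itertools import product

import numpy as np
import pandas as pd
import pytest

from paradiverge.io_formats import STRESSES, DERecord, ParalogPair
from paradiverge.patterns import (
    DEIndex,
    assign_cluster,
    call_de,
    classify_pair,
    classify_pairs,
    classify_trajectory,
    coexpressed_fraction,
    pattern_counts,
    trajectory_table,
)
from paradiverge.simulate import SimulationConfig, simulate_dataset, simulate_expression


def _rec(gene, stress="Dr", t=3, lfc=2.0, padj=0.01, expressed=True):
    return DERecord(gene, stress, t, lfc, padj, expressed)


class TestCallDe:
    def test_passing_call(self):
        assert call_de(_rec("g", lfc=-2.0, padj=0.01))

    @pytest.mark.parametrize(
        "lfc, padj, expressed",
        [
            (3.0, 0.05, True),  # padj at boundary: strict inequality fails
            (1.0, 0.01, True),  # |log2FC| at boundary: strict inequality fails
            (3.0, 0.01, False),  # not expressed
        ],
    )
    def test_strict_boundaries(self, lfc, padj, expressed):
        assert not call_de(_rec("g", lfc=lfc, padj=padj, expressed=expressed))

    def test_missing_record_is_not_de(self):
        assert not call_de(None)


class TestClassifyPair:
    @pytest.fixture
    def pair(self):
        return ParalogPair("p1", "gA", "gB", "TTTAAA", "TTTAAG")

    def test_both_de_is_ff(self, pair):
        idx = DEIndex([_rec("gA"), _rec("gB")])
        assert classify_pair(pair, ("Dr", 3), idx) == "FF"

    def test_one_de_is_fp(self, pair):
        idx = DEIndex([_rec("gA")])
        assert classify_pair(pair, ("Dr", 3), idx) == "FP"

    def test_neither_de_is_pp(self, pair):
        idx = DEIndex([_rec("gA", padj=0.9)])
        assert classify_pair(pair, ("Dr", 3), idx) == "PP"

    def test_partition_property(self, pair):
        """Every pair gets exactly one of FF/FP/PP under every condition."""
        for de_a, de_b in product([True, False], repeat=2):
            recs = []
            if de_a:
                recs.append(_rec("gA"))
            if de_b:
                recs.append(_rec("gB"))
            pattern = classify_pair(pair, ("Dr", 3), DEIndex(recs))
            assert pattern in {"FF", "FP", "PP"}
            assert pattern == {(True, True): "FF", (False, False): "PP"}.get(
                (de_a, de_b), "FP")


class TestAssignCluster:
    def test_all_fifteen_membership_sets(self):
        expected = {
            frozenset(STRESSES): "all_four",
            frozenset({"Dr", "Cd"}): "abiotic_shared",
            frozenset({"Bc", "Pr"}): "biotic_shared",
            frozenset({"Dr"}): "Dr_specific",
            frozenset({"Cd"}): "Cd_specific",
            frozenset({"Bc"}): "Bc_specific",
            frozenset({"Pr"}): "Pr_specific",
        }
        subsets = []
        for mask in range(1, 16):
            subsets.append(frozenset(s for i, s in enumerate(STRESSES) if mask & (1 << i)))
        for sub in subsets:
            assert assign_cluster("p", sub) == expected.get(sub, "other")

    def test_mixed_biotic_abiotic_is_other(self):
        assert assign_cluster("p", {"Dr", "Bc"}) == "other"

    def test_empty_membership_rejected(self):
        with pytest.raises(ValueError, match="empty membership"):
            assign_cluster("p", set())


class TestClassifyTrajectory:
    @pytest.mark.parametrize(
        "ranks, expected",
        [
            ((0, 1, 2), "enhancing"),
            ((0, 0, 2), "enhancing"),
            ((1, 2, 2), "enhancing"),
            ((2, 1, 0), "decreasing"),
            ((2, 2, 0), "decreasing"),
            ((1, 0, 2), "mixed"),
            ((2, 2, 2), "stable"),  # stable FF is not an arrowed change
            ((0, 0, 0), "stable"),
        ],
    )
    def test_labels(self, ranks, expected):
        assert classify_trajectory(ranks) == expected

    def test_time_reversal_swaps_enhancing_and_decreasing(self):
        swap = {"enhancing": "decreasing", "decreasing": "enhancing",
                "stable": "stable", "mixed": "mixed"}
        for ranks in product((0, 1, 2), repeat=3):
            assert classify_trajectory(ranks[::-1]) == swap[classify_trajectory(ranks)]

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_trajectory((0, 3, 2))


class TestCoexpressedFraction:
    def _setup(self, coupling_lambda, n=100, seed=0):
        cfg = SimulationConfig(n_pairs=n, coupling_lambda=coupling_lambda,
                               seed=seed, stresses=("Dr",), n_replicates=4)
        rng = np.random.default_rng(seed)
        pairs = [ParalogPair(f"P{i}", f"P{i}a", f"P{i}b", "TTTAAA", "TTTAAG")
                 for i in range(n)]
        expr = simulate_expression(pairs, np.full(n, 0.5), cfg, rng)
        return pairs, expr

    def test_perfectly_coupled_pairs_nearly_all_coexpressed(self):
        pairs, expr = self._setup(coupling_lambda=0.0)
        assert coexpressed_fraction(pairs, expr, stress="Dr") >= 0.95

    def test_anticorrelated_pairs_score_zero(self):
        pairs, expr = self._setup(coupling_lambda=0.0, n=10)
        # plant exactly anticorrelated log profiles: r = -1 for every pair
        base = np.linspace(1.0, 2.0, expr.values.shape[1])
        for p in pairs:
            expr.values.loc[p.gene_a] = np.expm1(base)
            expr.values.loc[p.gene_b] = np.expm1(3.0 - base)
        assert coexpressed_fraction(pairs, expr, stress="Dr") == 0.0

    def test_empty_subset_rejected(self):
        pairs, expr = self._setup(coupling_lambda=0.0, n=5)
        with pytest.raises(ValueError, match="empty"):
            coexpressed_fraction(pairs, expr, subset=set())


class TestPatternCounts:
    def test_all_pp(self):
        pairs = [ParalogPair(f"P{i}", f"P{i}a", f"P{i}b", "TTTAAA", "TTTAAG")
                 for i in range(10)]
        calls = classify_pairs(pairs, [], conditions=[("Dr", 3)])
        counts = pattern_counts(calls)
        row = counts.iloc[0]
        assert (row["FF"], row["FP"], row["PP"]) == (0, 0, 10)

    def test_counts_sum_to_n_pairs(self, small_dataset):
        calls = classify_pairs(small_dataset.pairs, small_dataset.de_records)
        counts = pattern_counts(calls)
        assert (counts[["FF", "FP", "PP"]].sum(axis=1) == len(small_dataset.pairs)).all()

    def test_independent_de_gives_binomial_split(self):
        """With independent per-gene DE at 0.5, FF/FP/PP fractions approach
        0.25 / 0.5 / 0.25."""
        cfg = SimulationConfig(n_pairs=2000, de_fraction=0.5, seed=11,
                               stresses=("Dr",), n_timepoints=1, codons_per_gene=2,
                               target_ks=0.0, ks_range=None)
        ds = simulate_dataset(cfg)
        calls = classify_pairs(ds.pairs, ds.de_records)
        counts = pattern_counts(calls).iloc[0]
        assert counts["FF"] / 2000 == pytest.approx(0.25, abs=0.05)
        assert counts["FP"] / 2000 == pytest.approx(0.50, abs=0.05)
        assert counts["PP"] / 2000 == pytest.approx(0.25, abs=0.05)
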