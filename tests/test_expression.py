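"""Normalization, fold-change, commonality, synergy and enrichment statistics."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cobindsi import expression as xp
from cobindsi.core import CountMatrix
from cobindsi.fixtures import load_table1


def _cm(columns: dict, conditions: list, cell_type="VSMC"):
    samples = pd.DataFrame(
        {
            "sample": list(columns),
            "cell_type": [cell_type] * len(columns),
            "condition": conditions,
            "replicate": list(range(1, len(columns) + 1)),
        }
    )
    counts = pd.DataFrame(columns, index=[f"g{i}" for i in range(len(next(iter(columns.values()))))])
    return CountMatrix(counts, samples)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm({"a": [5, 9, 3], "b": [5, 9, 3]}, ["control", "LPS"])
        assert np.allclose(xp.size_factors(cm), 1.0)

    def test_hand_median_of_ratios(self):
        # [[10,20],[100,200],[4,8]] -> (1/sqrt(2), sqrt(2))
        cm = _cm({"a": [10, 100, 4], "b": [20, 200, 8]}, ["control", "LPS"])
        f = xp.size_factors(cm)
        assert f["a"] == pytest.approx(1 / math.sqrt(2))
        assert f["b"] == pytest.approx(math.sqrt(2))

    def test_doubling_a_column_doubles_its_relative_factor(self):
        cm1 = _cm({"a": [10, 100, 4], "b": [20, 200, 8]}, ["control", "LPS"])
        cm2 = _cm({"a": [20, 200, 8], "b": [20, 200, 8]}, ["control", "LPS"])
        r1 = xp.size_factors(cm1)["a"] / xp.size_factors(cm1)["b"]
        r2 = xp.size_factors(cm2)["a"] / xp.size_factors(cm2)["b"]
        assert r2 == pytest.approx(2 * r1)

    def test_no_all_positive_gene_is_an_error(self):
        cm = _cm({"a": [0, 5], "b": [5, 0]}, ["control", "LPS"])
        with pytest.raises(ValueError, match="positive"):
            xp.size_factors(cm)


class TestNormalizeFilter:
    @pytest.mark.parametrize(
        "treated,included", [(8, False), (9, True)]  # strict > 8 boundary
    )
    def test_expressed_cutoff_boundary(self, treated, included):
        cm = _cm({"c": [8, 100], "t": [treated, 100]}, ["control", "LPS"])
        _, expressed = xp.normalize_and_filter(cm, pd.Series(1.0, index=["c", "t"]))
        assert ("g0" in expressed["VSMC"]) is included

    def test_zero_cutoff_admits_any_signal(self):
        cm = _cm({"c": [1, 100], "t": [0, 100]}, ["control", "LPS"])
        _, expressed = xp.normalize_and_filter(
            cm, pd.Series(1.0, index=["c", "t"]), cutoff=0.0
        )
        assert "g0" in expressed["VSMC"]


class TestFoldChanges:
    def test_missing_condition_is_named(self):
        cm = _cm({"c": [1], "t": [2]}, ["control", "LPS"])
        factors = pd.Series(1.0, index=cm.counts.columns)
        normalized, expressed = xp.normalize_and_filter(cm, factors)
        with pytest.raises(ValueError, match="IFNa"):
            xp.fold_changes(cm, normalized, expressed)

    def test_hand_fold_change_values(self):
        cm = _full_matrix(control=[10, 10, 0], treated={"LPS": [40, 10, 10]})
        factors = pd.Series(1.0, index=cm.counts.columns)
        normalized, expressed = xp.normalize_and_filter(cm, factors, cutoff=0.0)
        records = xp.fold_changes(cm, normalized, expressed)
        by_gene = {r.gene_id: r for r in records}
        assert by_gene["g0"].fc["LPS"] == pytest.approx(40.5 / 10.5)  # ~3.857
        assert by_gene["g1"].fc["LPS"] == pytest.approx(1.0)
        assert by_gene["g2"].fc["LPS"] == pytest.approx(21.0)  # 0 -> 10 with eps=.5

    def test_up_boundary_fc_exactly_two_included(self):
        # control mean 10, LPS mean 20.5 -> FC = 21/10.5 = 2 exactly
        cm = _full_matrix(control=[10], treated={"LPS": [20]})
        counts = cm.counts.copy()
        counts.loc["g0", "LPS_r2"] = 21
        cm = CountMatrix(counts, cm.samples)
        factors = pd.Series(1.0, index=cm.counts.columns)
        normalized, expressed = xp.normalize_and_filter(cm, factors, cutoff=0.0)
        rec = xp.fold_changes(cm, normalized, expressed)[0]
        assert rec.fc["LPS"] == pytest.approx(2.0)
        assert rec.up["LPS"]

    def test_up_lists_invariant_under_global_rescaling(self):
        cm1 = _full_matrix(control=[10, 50], treated={"LPS": [40, 50], "IFNa": [90, 50]})
        cm2 = CountMatrix(cm1.counts * 3, cm1.samples)
        lists = []
        for cm in (cm1, cm2):
            factors = xp.size_factors(cm)
            normalized, expressed = xp.normalize_and_filter(cm, factors, cutoff=0.0)
            lists.append(xp.up_regulated_lists(xp.fold_changes(cm, normalized, expressed)))
        assert lists[0] == lists[1]


def _full_matrix(control, treated: dict):
    """Counts for all 6 conditions of one cell type; unlisted conditions = control."""
    conditions = ["control", "IFNa", "IFNg", "LPS", "IFNa_LPS", "IFNg_LPS"]
    columns, labels = {}, []
    for cond in conditions:
        vals = treated.get(cond, control)
        for rep in (1, 2):
            columns[f"{cond}_r{rep}"] = vals
            labels.append(cond)
    return _cm(columns, labels)


class TestCommonGenes:
    def test_enumeration_oracle(self):
        common, venn = xp.common_genes([["a", "b", "c"], ["b", "c", "d"], ["c", "e"]])
        assert common == {"c"}
        assert sum(venn.values()) == 5
        assert venn["111"] == 1 and venn["110"] == 1 and venn["001"] == 1

    def test_identical_lists(self):
        common, venn = xp.common_genes([["x", "y"]] * 3)
        assert common == {"x", "y"}
        assert venn["111"] == 2 and sum(venn.values()) == 2

    def test_disjoint_lists(self):
        common, venn = xp.common_genes([["a"], ["b"], ["c"]])
        assert common == set()
        assert venn["100"] == venn["010"] == venn["001"] == 1

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.sampled_from("abcdefgh"), max_size=8),
        st.lists(st.sampled_from("abcdefgh"), max_size=8),
        st.lists(st.sampled_from("abcdefgh"), max_size=8),
    )
    def test_venn_partitions_union(self, a, b, c):
        common, venn = xp.common_genes([a, b, c])
        assert sum(venn.values()) == len(set(a) | set(b) | set(c))
        assert common == set(a) & set(b) & set(c)


class TestSIFlags:
    @pytest.mark.parametrize(
        "fc_ifn,fc_lps,fc_combo,expected",
        [
            (4.9, 90.9, 287.1, True),     # Nos2: strongly super-additive
            (356.3, 4.4, 343.7, False),   # Ifi44: below the FC sum
            (213.7, 2.2, 194.9, False),   # Apod: below the FC sum
        ],
    )
    def test_published_fc_triples(self, fc_ifn, fc_lps, fc_combo, expected):
        table = pd.DataFrame(
            {"fc_ifn": [fc_ifn], "fc_lps": [fc_lps], "fc_combo": [fc_combo]}
        )
        assert bool(xp.si_flags_from_fc(table).iloc[0]) is expected

    def test_si_records_match_strict_inequality(self):
        cm = _full_matrix(
            control=[10], treated={"IFNa": [40], "LPS": [40], "IFNa_LPS": [90]}
        )
        factors = pd.Series(1.0, index=cm.counts.columns)
        normalized, expressed = xp.normalize_and_filter(cm, factors, cutoff=0.0)
        records = xp.fold_changes(cm, normalized, expressed)
        si = [r for r in xp.si_flags(records) if r.combo == "IFNa_LPS"]
        # fc_combo = 90.5/10.5 ~ 8.62 > 3.857 + 3.857
        assert si[0].si_flag


class TestPairwiseOverlap:
    def test_jaccard_reproduces_published_common_overlap(self):
        a = {f"g{i}" for i in range(579)}
        b = {f"g{i}" for i in range(143, 143 + 536)}  # intersection 436
        assert len(a & b) == 436
        assert xp.pairwise_overlap(a, b, "jaccard") == pytest.approx(64.21, abs=0.005)

    def test_sum_method_reproduces_published_mode_overlap(self):
        a = {f"g{i}" for i in range(81)}
        b = {f"g{i}" for i in range(44, 44 + 45)}  # intersection 37
        assert xp.pairwise_overlap(a, b, "sum") == pytest.approx(29.37, abs=0.005)

    def test_disjoint_and_empty(self):
        assert xp.pairwise_overlap({"a"}, {"b"}, "jaccard") == 0.0
        assert xp.pairwise_overlap(set(), set(), "sum") == 0.0


class TestEnrichment:
    def test_set_equals_universe_p_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        table = xp.enrich_gene_sets(
            universe[:4], universe, {"all": ("", universe)}
        )
        assert table.loc[0, "p_value"] == pytest.approx(1.0)
        assert table.loc[0, "overlap"] == 4

    def test_exhaustive_enumeration_oracle(self):
        # universe 10, set 5, list 5, overlap 5 -> 1 / C(10,5)
        universe = [f"g{i}" for i in range(10)]
        table = xp.enrich_gene_sets(
            universe[:5], universe, {"s": ("", universe[:5])}
        )
        exact = 1 / math.comb(10, 5)
        assert table.loc[0, "p_value"] == pytest.approx(exact)
        # independent enumeration over all C(10,5) draws
        count = sum(
            1 for draw in combinations(range(10), 5) if len(set(draw) & set(range(5))) >= 5
        )
        assert exact == count / math.comb(10, 5)

    def test_zero_overlap_p_near_one(self):
        universe = [f"g{i}" for i in range(100)]
        table = xp.enrich_gene_sets(
            universe[:10], universe, {"s": ("", universe[90:])}
        )
        assert table.loc[0, "p_value"] > 0.3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            xp.enrich_gene_sets([], [], {"s": ("", ["x"])})


class TestExpressionSummary:
    def test_log2_and_quartiles(self):
        cm = _full_matrix(control=[10] * 4, treated={"LPS": [20] * 4})
        counts = cm.counts.copy()
        counts.loc[:, "LPS_r2"] = 21  # replicate mean 20.5 -> FC exactly 2
        cm = CountMatrix(counts, cm.samples)
        factors = pd.Series(1.0, index=cm.counts.columns)
        normalized, expressed = xp.normalize_and_filter(cm, factors, cutoff=0.0)
        records = xp.fold_changes(cm, normalized, expressed)
        matrix, q = xp.expression_summary(records, [r.gene_id for r in records], "VSMC")
        assert matrix["LPS"].iloc[0] == pytest.approx(1.0)  # FC 2 -> log2 FC 1
        assert q.loc["median", "LPS"] == pytest.approx(1.0)
        assert (q.loc["q3"] - q.loc["q1"])["LPS"] == pytest.approx(0.0)

    def test_quartile_convention_linear_interpolation(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert values.quantile(0.5) == pytest.approx(2.5)


def test_published_tables_ship_with_consistent_flags():
    """The packaged top-30 tables agree internally with the SI definition."""
    for which, n_expected in (("a", 25), ("b", 26)):
        table = load_table1(which)
        flags = xp.si_flags_from_fc(table)
        assert int(flags.sum()) == n_expected
        assert (flags.astype(int) == table["si_marked"]).all()
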