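import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ribosel.io import TranscriptCatalog, build_transcript
from ribosel.isoform import (
    IsoformUsage,
    adjust_selection_pvalues,
    analyze_condition,
    build_isoform_usage,
    call_dominant_transcript,
    compare_structural_elements,
    detect_dominant_switch,
    diff_cp,
    extreme_isoforms,
    isoform_proportions,
    multi_isoform_stats,
    proportion_test,
    selective_usage_test,
)

from conftest import make_table


def usage(counts_cyto, counts_ribo, ids=None):
    k = len(counts_cyto)
    ids = tuple(ids or (f"t{i+1}" for i in range(k)))
    cc = np.asarray(counts_cyto, dtype=float)
    cr = np.asarray(counts_ribo, dtype=float)
    return IsoformUsage(
        gene_id="g", transcript_ids=ids,
        counts_cyto=cc, counts_ribo=cr,
        cp_cyto=cc / cc.sum() if cc.sum() else cc,
        cp_ribo=cr / cr.sum() if cr.sum() else cr,
    )


def pearson_chi2(table: np.ndarray) -> float:
    """Independent brute-force Pearson statistic Σ(O−E)²/E over all cells."""
    table = np.asarray(table, dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestIsoformProportions:
    def table(self):
        return make_table(
            {
                "g1.t1": {"A_cyto": 60, "A_ribo": 90},
                "g1.t2": {"A_cyto": 40, "A_ribo": 10},
                "g2.t1": {"A_cyto": 100, "A_ribo": 100},
            },
            {"g1.t1": "g1", "g1.t2": "g1", "g2.t1": "g2"},
            totals={l: 100_000 for l in ("A_cyto", "A_ribo", "B_cyto", "B_ribo")},
        )

    def test_single_isoform_gene(self):
        cp = isoform_proportions(self.table(), "g2", "A", "cytosolic")
        assert list(cp.index) == ["g2.t1"] and cp.iloc[0] == 1.0

    def test_two_isoform_split(self):
        cp = isoform_proportions(self.table(), "g1", "A", "cytosolic")
        assert np.allclose(cp, [0.6, 0.4])

    def test_filtered_isoform_renormalized(self):
        t = make_table(
            {
                "g1.t1": {"A_cyto": 60},
                "g1.t2": {"A_cyto": 40},
                "g1.t3": {"A_cyto": 0.05},  # FPKM 0.5 at these totals: filtered
            },
            {f"g1.t{i}": "g1" for i in (1, 2, 3)},
            totals={l: 100_000 for l in ("A_cyto", "A_ribo", "B_cyto", "B_ribo")},
        )
        cp = isoform_proportions(t, "g1", "A", "cytosolic", min_tx_fpkm=1.0)
        assert list(cp.index) == ["g1.t1", "g1.t2"]
        assert np.allclose(cp, [0.6, 0.4])


class TestSelectiveUsageTest:
    def test_homogeneous_proportions_give_zero_statistic(self):
        res = selective_usage_test(usage([50, 50], [150, 150]), pseudocount=0.0, min_expected=0.0)
        assert res.chi2_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        obs = np.array([[50, 50], [90, 10]])
        res = selective_usage_test(usage(obs[0], obs[1]), pseudocount=0.0, min_expected=0.0)
        assert res.chi2_stat == pytest.approx(pearson_chi2(obs), abs=1e-10)
        assert res.df == 1

    def test_low_expectation_isoform_merged(self):
        # third isoform has expected counts ≈ 2 < 5: merged, df drops from 2 to 1
        res = selective_usage_test(usage([49, 49, 2], [49, 49, 2]), pseudocount=0.0, min_expected=5.0)
        assert res.df == 1 and res.k_merged == 2

    def test_single_isoform_not_testable(self):
        assert selective_usage_test(usage([100], [100])) is None

    def test_empty_fraction_not_testable(self):
        assert selective_usage_test(usage([100, 50], [0, 0]), pseudocount=0.0) is None

    @given(
        st.integers(2, 5).flatmap(
            lambda k: st.tuples(
                st.lists(st.integers(1, 500), min_size=k, max_size=k),
                st.lists(st.integers(1, 500), min_size=k, max_size=k),
            )
        )
    )
    def test_unmodified_statistic_equals_pearson(self, rows):
        cc, cr = rows
        obs = np.array([cc, cr], dtype=float)
        res = selective_usage_test(usage(cc, cr), pseudocount=0.0, min_expected=0.0)
        assert res.chi2_stat == pytest.approx(pearson_chi2(obs), abs=1e-9)
        assert res.df == len(cc) - 1


class TestAdjustment:
    def test_all_ones_no_selection(self):
        out = adjust_selection_pvalues(pd.Series([1.0, 1.0, 1.0]))
        assert not out["selected"].any()

    def test_bh_by_hand_on_three_values(self):
        out = adjust_selection_pvalues(pd.Series({"a": 0.001, "b": 0.02, "c": 0.9}), alpha=0.05)
        assert np.allclose(out["q_value"], [0.003, 0.03, 0.9])
        assert list(out["selected"]) == [True, True, False]

    def test_order_invariance(self):
        p = pd.Series({"a": 0.001, "b": 0.02, "c": 0.9})
        out1 = adjust_selection_pvalues(p)
        out2 = adjust_selection_pvalues(p.iloc[[2, 0, 1]])
        assert np.allclose(out1["q_value"].sort_index(), out2["q_value"].sort_index())


class TestDiffCp:
    def test_equal_cp_all_zero(self):
        assert np.allclose(diff_cp(usage([60, 40], [60, 40])), 0.0)

    def test_arithmetic(self):
        d = diff_cp(usage([50, 50], [80, 20]))
        assert np.allclose(d, [0.3, -0.3])

    @given(
        st.integers(2, 5).flatmap(
            lambda k: st.tuples(
                st.lists(st.integers(1, 1000), min_size=k, max_size=k),
                st.lists(st.integers(1, 1000), min_size=k, max_size=k),
            )
        )
    )
    def test_conservation(self, rows):
        cc, cr = rows
        assert abs(diff_cp(usage(cc, cr)).sum()) < 1e-9


class TestExtremeIsoforms:
    def test_two_isoform_case(self):
        d = pd.Series({"t1": 0.3, "t2": -0.3})
        assert extreme_isoforms(d) == ("t1", "t2")

    def test_tie_broken_by_cytosolic_cp(self):
        d = pd.Series({"t1": 0.2, "t2": 0.2, "t3": -0.4})
        cp = pd.Series({"t1": 0.5, "t2": 0.3, "t3": 0.2})
        assert extreme_isoforms(d, cp)[0] == "t1"

    def test_negation_swaps_pair(self):
        d = pd.Series({"t1": 0.25, "t2": -0.05, "t3": -0.2})
        pos, neg = extreme_isoforms(d)
        pos2, neg2 = extreme_isoforms(-d)
        assert (pos2, neg2) == (neg, pos)

    def test_degenerate_all_zero_returns_distinct_pair(self):
        d = pd.Series({"t1": 0.0, "t2": 0.0})
        pos, neg = extreme_isoforms(d)
        assert pos != neg


class TestStructuralComparison:
    def catalog(self):
        mk = build_transcript
        models = [
            mk("t1", "g", "c", "+", [(100, 200), (300, 500)], [(150, 200), (300, 400)]),
            # same CDS, longer 3'UTR
            mk("t2", "g", "c", "+", [(100, 200), (300, 600)], [(150, 200), (300, 400)]),
            # identical structure to t1
            mk("t3", "g", "c", "+", [(100, 200), (300, 500)], [(150, 200), (300, 400)]),
            # extra 5' exon entirely upstream of the CDS
            mk("t4", "g", "c", "+", [(20, 60), (100, 200), (300, 500)], [(150, 200), (300, 400)]),
            mk("t5", "g", "c", "+", [(100, 200), (300, 500)]),  # non-coding
            mk("t6", "h", "c", "+", [(0, 100)], [(0, 100)]),
        ]
        return TranscriptCatalog.from_transcripts(models)

    def test_identical_transcript_empty_set(self):
        cat = self.catalog()
        assert compare_structural_elements("t1", "t1", cat) == set()
        assert compare_structural_elements("t1", "t3", cat) == set()

    def test_utr3_only_difference(self):
        assert compare_structural_elements("t1", "t2", self.catalog()) == {"utr3"}

    def test_extra_upstream_exon_is_utr5(self):
        assert compare_structural_elements("t1", "t4", self.catalog()) == {"utr5"}

    def test_noncoding_partner_reports_all_present_elements(self):
        assert compare_structural_elements("t1", "t5", self.catalog()) == {"utr5", "utr3", "cds"}

    def test_cross_gene_rejected(self):
        with pytest.raises(ValueError):
            compare_structural_elements("t1", "t6", self.catalog())


class TestMultiIsoformStats:
    def test_proportions(self):
        t = make_table(
            {
                "g1.t1": {"A_cyto": 500}, "g1.t2": {"A_cyto": 500},
                "g2.t1": {"A_cyto": 1000},
                "g3.t1": {"A_cyto": 900}, "g3.t2": {"A_cyto": 0.01},
            },
            {"g1.t1": "g1", "g1.t2": "g1", "g2.t1": "g2", "g3.t1": "g3", "g3.t2": "g3"},
            totals={l: 1e6 for l in ("A_cyto", "A_ribo", "B_cyto", "B_ribo")},
        )
        out = multi_isoform_stats(t, "A", "cytosolic")
        assert out["n_genes_total"] == 3
        assert out["n_genes_ge2_expressed"] == 1  # g3.t2 fails the FPKM filter
        assert out["proportion"] == pytest.approx(1 / 3)


class TestProportionTest:
    def test_equal_proportions_p_one(self):
        assert proportion_test(30, 100, 30, 100) == pytest.approx(1.0)

    def test_matches_yates_oracle(self):
        x1, n1, x2, n2 = 40, 100, 20, 100
        obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat = (((np.abs(obs - expected) - 0.5).clip(min=0) ** 2) / expected).sum()
        from scipy.stats import chi2

        assert proportion_test(x1, n1, x2, n2) == pytest.approx(chi2.sf(stat, 1), abs=1e-10)

    def test_symmetric_in_samples(self):
        assert proportion_test(40, 100, 20, 90) == pytest.approx(proportion_test(20, 90, 40, 100))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_test(11, 10, 1, 10)


class TestDominant:
    def test_single_isoform_dominant(self):
        assert call_dominant_transcript(pd.Series({"t1": 1.0})) == "t1"

    def test_rule_arithmetic(self):
        assert call_dominant_transcript(pd.Series({"t1": 0.7, "t2": 0.2, "t3": 0.1})) == "t1"

    def test_fails_cp_min(self):
        assert call_dominant_transcript(pd.Series({"t1": 0.45, "t2": 0.44, "t3": 0.11})) is None

    def test_fails_ratio(self):
        assert call_dominant_transcript(pd.Series({"t1": 0.55, "t2": 0.45})) is None

    def test_switch_detection(self):
        assert detect_dominant_switch("t1", "t1") == "unchanged"
        assert detect_dominant_switch("t1", "t2") == "switched"
        assert detect_dominant_switch("t1", None) == "undefined"


class TestAnalyzeCondition:
    def test_driver_consistent_with_primitives(self, default_sim):
        _, catalog, _, table, _ = default_sim
        genes, iso = analyze_condition(table, catalog, "A")
        # q-values only on testable genes; selected implies testable
        assert genes.loc[genes["selected"], "testable"].all()
        assert genes.loc[~genes["testable"], "q_value"].isna().all()
        # per-isoform Diff_CP conserves mass within each gene
        sums = iso.groupby("gene_id")["diff_cp"].sum()
        assert (sums.abs() < 1e-9).all()
        # extremes match the per-isoform table
        for g, sub in iso.groupby("gene_id"):
            row = genes.loc[g]
            sub = sub.set_index("transcript_id")
            assert row["max_pos_tx"] in sub.index and row["max_neg_tx"] in sub.index
            assert sub["diff_cp"][row["max_pos_tx"]] == sub["diff_cp"].max()
            assert sub["diff_cp"][row["max_neg_tx"]] == sub["diff_cp"].min()

    def test_usage_matches_proportions_op(self, default_sim):
        _, _, _, table, _ = default_sim
        gene = table.tx2gene[table.tx2gene.duplicated()].iloc[0]
        u = build_isoform_usage(table, gene, "A")
        cp = isoform_proportions(table, gene, "A", "cytosolic")
        got = pd.Series(u.cp_cyto, index=list(u.transcript_ids)).reindex(cp.index)
        assert np.allclose(got, cp)
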