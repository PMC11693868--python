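import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import gammaln

from ribosel.expression import (
    DifferentialThresholds,
    call_differential,
    compute_fpkm,
    fisher_count_test,
    overlap_calls,
)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact by explicit hypergeometric tail enumeration:
    the sum of all table probabilities not exceeding the observed one
    (standard minimum-likelihood convention, with a relative float guard)."""
    n1, n2, ncol = a + b, c + d, a + c
    N = n1 + n2

    def logpmf(k):
        return (
            gammaln(n1 + 1) - gammaln(k + 1) - gammaln(n1 - k + 1)
            + gammaln(n2 + 1) - gammaln(ncol - k + 1) - gammaln(n2 - ncol + k + 1)
            + gammaln(ncol + 1) + gammaln(N - ncol + 1) - gammaln(N + 1)
        )

    ks = np.arange(max(0, ncol - n2), min(ncol, n1) + 1)
    lp = logpmf(ks.astype(float))
    obs = float(logpmf(np.array([float(a)]))[0])
    return float(np.exp(lp[lp <= obs + 1e-7]).sum())


class TestComputeFpkm:
    def test_direct_formula(self):
        counts = pd.DataFrame({"L": [100.0]}, index=["t1"])
        fpkm = compute_fpkm(counts, pd.Series({"t1": 1000.0}), pd.Series({"L": 1e6}))
        assert fpkm.loc["t1", "L"] == pytest.approx(100.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"L": [0.0]}, index=["t1"])
        fpkm = compute_fpkm(counts, pd.Series({"t1": 500.0}), pd.Series({"L": 1e6}))
        assert fpkm.loc["t1", "L"] == 0.0

    def test_scale_invariance(self):
        counts = pd.DataFrame({"L": [100.0, 7.0]}, index=["t1", "t2"])
        lens = pd.Series({"t1": 1000.0, "t2": 300.0})
        f1 = compute_fpkm(counts, lens, pd.Series({"L": 1e6}))
        f2 = compute_fpkm(2 * counts, lens, pd.Series({"L": 2e6}))
        assert np.allclose(f1, f2)

    def test_bad_length_rejected(self):
        counts = pd.DataFrame({"L": [1.0]}, index=["t1"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"t1": 0.0}), pd.Series({"L": 1e6}))


class TestFisher:
    def test_matches_enumeration_oracle_on_deep_table(self):
        p = fisher_count_test(30, 1_000_000, 5, 1_000_000)
        assert p == pytest.approx(fisher_oracle(30, 999_970, 5, 999_995), abs=1e-12)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_matches_enumeration_oracle_on_small_tables(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p = fisher_count_test(a, a + b, c, c + d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_count_above_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_count_test(10, 5, 1, 100)


def two_library_calls(counts_a, counts_b, total_a=1_000_000, total_b=1_000_000, **kw):
    genes = [f"g{i}" for i in range(len(counts_a))]
    ca = pd.Series(counts_a, index=genes, dtype=float)
    cb = pd.Series(counts_b, index=genes, dtype=float)
    # FPKM with length 1000 nt: count × 10⁹ / (1000 × total)
    fa = ca * 1e9 / (1000 * total_a)
    fb = cb * 1e9 / (1000 * total_b)
    return call_differential(ca, cb, fa, fb, total_a, total_b, **kw)


class TestCallDifferential:
    def test_identical_libraries_all_ns(self):
        calls = two_library_calls([5000, 300, 10], [5000, 300, 10])
        assert (calls["flag"] == "ns").all()
        assert np.allclose(calls["log2fc"], 0.0)

    def test_all_three_criteria_required(self):
        # gene with FPKM (2.0, 0.4): |log2fc| ≈ 2.2 and max FPKM ≥ 1, so the
        # call rests entirely on p_adj — identical small counts cannot reach it
        calls = two_library_calls([2000, 400000], [400, 400000])
        g = calls.loc["g0"]
        assert abs(g["log2fc"]) >= 1 and max(g["fpkm_A"], g["fpkm_B"]) >= 1
        assert (g["flag"] != "ns") == (g["p_adj"] <= 0.001)

    def test_low_expression_excluded_from_family(self):
        calls = two_library_calls([0.4, 5000], [0.1, 5000])
        assert not calls.loc["g0", "expressed"]
        assert np.isnan(calls.loc["g0", "p_raw"])
        assert calls.loc["g0", "flag"] == "ns"

    def test_direction_flags(self):
        calls = two_library_calls([100000, 1000], [1000, 100000])
        assert calls.loc["g0", "flag"] == "up_A"
        assert calls.loc["g1", "flag"] == "up_B"

    def test_flags_antisymmetric_under_condition_swap(self):
        a = [50000, 120, 7000, 900, 33000]
        b = [900, 120, 56000, 900, 33]
        fwd = two_library_calls(a, b)
        rev = two_library_calls(b, a)
        swap = {"up_A": "up_B", "up_B": "up_A", "ns": "ns"}
        assert list(rev["flag"]) == [swap[f] for f in fwd["flag"]]

    def test_bh_adjustment_is_monotone(self):
        calls = two_library_calls(
            [5000, 5200, 6000, 4000, 100], [5000, 5100, 4000, 6100, 4000]
        )
        tested = calls.dropna(subset=["p_raw"]).sort_values("p_raw")
        assert tested["p_adj"].is_monotonic_increasing
        assert (tested["p_adj"] >= tested["p_raw"] - 1e-12).all()

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            two_library_calls([1], [1], total_a=0)


class TestOverlap:
    def test_disjoint(self):
        assert overlap_calls({"a"}, {"b"})["n_shared"] == 0

    def test_identical(self):
        ov = overlap_calls({"a", "b"}, {"a", "b"})
        assert ov["frac_of_deg"] == 1.0 and ov["frac_of_dtg"] == 1.0

    def test_published_scale_fractions(self):
        deg = {f"g{i}" for i in range(2267)}
        dtg = {f"g{i}" for i in range(498, 2750)}  # size 2252, overlap 1769
        ov = overlap_calls(deg, dtg)
        assert ov["n_deg"] == 2267 and ov["n_dtg"] == 2252 and ov["n_shared"] == 1769
        assert ov["frac_of_deg"] == pytest.approx(1769 / 2267)
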