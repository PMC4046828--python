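"""Exact test, FDR, calls, categories and trend classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import nbinom

from tagdge.datasets import ripening_profiles
from tagdge.de import (
    GROUP_CONSTITUTIVE,
    GROUP_DOWN,
    GROUP_MID_PEAK,
    GROUP_UP,
    DGEResults,
    PairwiseDGE,
    ac_pvalue,
    bh_fdr,
    call_de,
    categorize,
    classify_pattern,
    log2_ratio,
)
from tagdge.errors import InputError


def nbinom_pvalue(x, y, n1, n2):
    """Independent route: the conditional is NB(x+1, N1/(N1+N2))."""
    q = n1 / (n1 + n2)
    F = nbinom.cdf(y, x + 1, q)
    return min(1.0, 2.0 * min(F, 1.0 - F))


class TestAcPvalue:
    def test_equal_counts_equal_totals_is_one(self):
        assert ac_pvalue(7, 7, 1e6, 1e6) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_five_zero(self):
        # p(0|5) at r=1 is 2^-6; the lower tail is the single term
        assert ac_pvalue(5, 0, 1e6, 1e6) == pytest.approx(0.03125, abs=1e-12)

    def test_symmetry_worked_example(self):
        a = ac_pvalue(3, 10, 1e6, 2e6)
        b = ac_pvalue(10, 3, 2e6, 1e6)
        assert a == pytest.approx(b, abs=1e-12)

    @given(
        st.integers(0, 150),
        st.integers(0, 150),
        st.sampled_from([1e5, 1e6, 5e6]),
        st.sampled_from([1e5, 1e6, 5e6]),
    )
    def test_symmetry_property(self, x, y, n1, n2):
        assert ac_pvalue(x, y, n1, n2) == pytest.approx(
            ac_pvalue(y, x, n2, n1), abs=1e-12
        )

    @given(
        st.integers(0, 120),
        st.integers(0, 120),
        st.sampled_from([1e5, 1e6, 5e6]),
        st.sampled_from([1e5, 1e6, 5e6]),
    )
    def test_matches_negative_binomial_identity(self, x, y, n1, n2):
        assert ac_pvalue(x, y, n1, n2) == pytest.approx(
            nbinom_pvalue(x, y, n1, n2), abs=1e-9
        )

    @given(st.integers(0, 60))
    def test_monotone_in_count_distance(self, x):
        pvals = [ac_pvalue(x, y, 1e6, 1e6) for y in range(x, x + 40)]
        assert all(a >= b - 1e-12 for a, b in zip(pvals, pvals[1:]))

    def test_large_counts_stable(self):
        p = ac_pvalue(5000, 5200, 5e6, 5e6)
        assert 0 < p <= 1
        assert p == pytest.approx(nbinom_pvalue(5000, 5200, 5e6, 5e6), abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(InputError):
            ac_pvalue(-1, 0, 1e6, 1e6)
        with pytest.raises(InputError):
            ac_pvalue(0, 0, 0, 1e6)


class TestBhFdr:
    def test_single_value_identity(self):
        assert bh_fdr([0.004]) == pytest.approx([0.004])

    def test_hand_executed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_ties_all_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_permutation_invariant(self, pvals):
        adj = bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(pvals))
        adj_perm = bh_fdr(np.asarray(pvals)[perm])
        assert np.allclose(np.sort(adj_perm), np.sort(adj))


class TestLog2Ratio:
    def test_equal(self):
        assert log2_ratio(12.5, 12.5) == 0.0

    def test_worked_value(self):
        assert log2_ratio(6.68, 159) == pytest.approx(math.log2(159 / 6.68), rel=1e-12)

    def test_zero_substitution(self):
        assert log2_ratio(0, 8.192) == pytest.approx(13.0, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            log2_ratio(-1, 2)


class TestCallDe:
    def test_both_criteria_met(self):
        assert call_de([0.0005], [3.0])[0] == "up"
        assert call_de([0.0005], [-3.0])[0] == "down"

    def test_effect_below_threshold(self):
        assert call_de([0.0005], [0.5])[0] == "ns"

    def test_fdr_above_threshold(self):
        assert call_de([0.01], [5.0])[0] == "ns"

    def test_custom_thresholds(self):
        assert call_de([0.01], [2.5], fdr_max=0.05, min_abs_log2=2.0)[0] == "up"


class TestCategorize:
    @pytest.mark.parametrize(
        "tpm, cat",
        [
            (0, "rare"), (3, "rare"), (4.999, "rare"),
            (5, "low"), (49.9, "low"),
            (50, "moderate"), (99.99, "moderate"),
            (100, "high"), (150, "high"),
        ],
    )
    def test_boundaries(self, tpm, cat):
        assert categorize(tpm) == cat


class TestClassifyPattern:
    def test_strictly_increasing_is_up(self):
        assert classify_pattern([1, 2, 4, 8, 16]).group == GROUP_UP

    def test_flat_is_constitutive(self):
        assert classify_pattern([5, 5, 5, 5, 5]).group == GROUP_CONSTITUTIVE

    def test_published_down_profile(self):
        assert classify_pattern([1120.57, 775.21, 201.84, 18.2, 5.7]).group == GROUP_DOWN

    def test_published_mid_peak_profile(self):
        assert classify_pattern([0.35, 1.61, 77.96, 17.7, 0]).group == GROUP_MID_PEAK

    def test_wrong_length_rejected(self):
        with pytest.raises(InputError):
            classify_pattern([1, 2, 3])

    def test_reference_panel_concordance(self):
        """The rule set reproduces >= 38 of the 39 published trend labels."""
        panel = ripening_profiles()
        hits = sum(
            classify_pattern(row[["fs1", "fs2", "fs3", "fs4", "fs5"]].to_numpy(float)).group
            == row["group"]
            for _, row in panel.iterrows()
        )
        assert hits >= 38


class TestPairwiseDGE:
    def test_fit_frame_and_counts(self):
        model = PairwiseDGE(
            counts_a=[100, 10, 0, 50],
            counts_b=[100, 80, 30, 49],
            total_a=1_000_000,
            total_b=1_000_000,
            gene_ids=list("abcd"),
        )
        res = model.fit(fdr_max=0.001, min_abs_log2=1.0)
        frame = res.frame.set_index("gene_id")
        assert res.n_up + res.n_down + res.n_ns == 4
        assert frame.loc["a", "call"] == "ns"
        assert frame.loc["b", "call"] == "up"
        assert frame.loc["b", "log2_ratio"] == pytest.approx(3.0)
        # FDR is step-up adjusted, never below the raw p
        assert (frame["fdr"] >= frame["pvalue"] - 1e-15).all()
        assert "up-regulated" in res.summary()

    def test_from_dataframe_round_trip(self):
        mat = pd.DataFrame(
            {"count_A": [5, 0], "count_B": [0, 9]}, index=["g1", "g2"]
        )
        model = PairwiseDGE.from_dataframe(mat, "A", "B", 10_000, 20_000)
        res = model.fit()
        assert list(res.frame["gene_id"]) == ["g1", "g2"]

    def test_zero_count_gene_uses_substituted_ratio(self):
        model = PairwiseDGE([0], [8], 1_000_000, 1_000_000)
        res = model.fit()
        assert res.frame["log2_ratio"].iloc[0] == pytest.approx(math.log2(8 / 0.001))

    def test_validation(self):
        with pytest.raises(InputError):
            PairwiseDGE([1, 2], [1], 10, 10)
        with pytest.raises(InputError):
            PairwiseDGE([5], [1], 2, 10)
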