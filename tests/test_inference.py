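"""Frequency chi-square, paired t, Bonferroni, and summary assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from limbasym import (
    bonferroni_alpha,
    format_p,
    frequency_chi_square,
    magnitude_paired_t,
    summarize_taxon,
)
from limbasym.inference import one_sample_pa_t
from conftest import make_sample

# Published count pairs with their continuity-corrected chi-square statistics
# (six pelvic samples, then three femoral ones).
GOLDEN_COUNTS = [
    (48, 70, 1.71, ".191"),
    (38, 57, 1.54, ".215"),
    (50, 39, 0.46, ".499"),
    (44, 47, 0.01, ".941"),
    (39, 41, 0.00, "1.000"),
    (23, 51, 4.74, ".030"),
    (22, 44, 3.12, ".077"),
    (44, 27, 1.61, ".205"),
    (39, 29, 0.47, ".492"),
]


def brute_force_corrected_chi2(n_left: int, n_right: int) -> float:
    """Independent oracle: explicit four-cell sum of (|O - E| - 0.5)^2 / E.

    Builds the same 2x2 table (observed counts over the 50:50 expectation) and
    loops over the four cells with margin-derived expectations, clamping the
    corrected deviation at zero.
    """
    e = (n_left + n_right) / 2
    table = [[n_left, n_right], [e, e]]
    total = n_left + n_right + 2 * e
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            row_sum = table[i][0] + table[i][1]
            col_sum = table[0][j] + table[1][j]
            expected = row_sum * col_sum / total
            dev = max(abs(table[i][j] - expected) - 0.5, 0.0)
            chi2 += dev**2 / expected
    return chi2


class TestFrequencyChiSquare:
    @pytest.mark.parametrize("n_left, n_right, chi2, p_str", GOLDEN_COUNTS)
    def test_golden_statistics(self, n_left, n_right, chi2, p_str):
        res = frequency_chi_square(n_left, n_right)
        assert round(res.chi2, 2) == chi2
        assert format_p(res.p) == p_str
        assert res.df == 1

    def test_plain_goodness_of_fit_does_not_match(self):
        """The uncorrected one-sample statistic is a different (larger) number."""
        res = frequency_chi_square(48, 70, method="uncorrected")
        assert round(res.chi2, 2) == 4.10
        assert round(res.chi2, 2) != 1.71

    @pytest.mark.parametrize("k", [1, 5, 50])
    def test_perfect_balance_gives_zero(self, k):
        assert frequency_chi_square(k, k).chi2 == 0.0

    @given(st.integers(min_value=0, max_value=200), st.integers(min_value=0, max_value=200))
    def test_swap_invariance(self, a, b):
        if a + b == 0:
            return
        assert frequency_chi_square(a, b).chi2 == pytest.approx(
            frequency_chi_square(b, a).chi2, abs=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            a, b = (int(x) for x in rng.integers(0, 201, 2))
            if a + b == 0:
                continue
            assert frequency_chi_square(a, b).chi2 == pytest.approx(
                brute_force_corrected_chi2(a, b), abs=1e-10
            )

    def test_matches_scipy_contingency_when_not_clamped(self, rng):
        """Cross-check against scipy's 2x2 Yates correction where |diff| >= 2
        (scipy does not clamp the corrected deviation at zero, so the two only
        agree away from near-balance)."""
        for _ in range(100):
            a, b = (int(x) for x in rng.integers(0, 150, 2))
            if abs(a - b) < 2:
                continue
            e = (a + b) / 2
            expected = stats.chi2_contingency([[a, b], [e, e]], correction=True)
            res = frequency_chi_square(a, b)
            assert res.chi2 == pytest.approx(expected.statistic, abs=1e-9)
            assert res.p == pytest.approx(expected.pvalue, abs=1e-9)

    def test_near_balance_is_clamped_to_zero(self):
        assert frequency_chi_square(40, 41).chi2 == 0.0
        assert frequency_chi_square(40, 41).p == 1.0

    def test_no_informative_individuals_error(self):
        with pytest.raises(ValueError, match="no informative"):
            frequency_chi_square(0, 0)

    def test_binomial_alternative(self):
        res = frequency_chi_square(2, 8, method="binomial")
        assert math.isnan(res.chi2)
        assert res.p == pytest.approx(stats.binomtest(2, 10, 0.5).pvalue)


class TestMagnitudePairedT:
    def test_hand_computed_small_cases(self):
        # d = (2, 0, 2, 0): mean 1, sd 2/sqrt(3) -> t = sqrt(3)
        res = magnitude_paired_t([10, 10, 10, 10], [12, 10, 12, 10])
        assert res.t == pytest.approx(1.732, abs=0.001)
        assert res.df == 3
        # d = (1, 3): mean 2, sd sqrt(2) -> t = 2
        res = magnitude_paired_t([10, 10], [11, 13])
        assert res.t == pytest.approx(2.0, abs=1e-12)
        assert res.df == 1

    def test_matches_scipy_ttest_rel(self, rng):
        left = rng.normal(10, 1, 30)
        right = left + rng.normal(0.2, 0.5, 30)
        mine = magnitude_paired_t(left, right)
        ref = stats.ttest_rel(right, left)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_sign_convention_right_larger_positive(self):
        res = magnitude_paired_t([10, 10, 10], [11, 12, 11.5])
        assert res.t > 0 and res.mean_pa > 0
        res = magnitude_paired_t([11, 12, 11.5], [10, 10, 10])
        assert res.t < 0 and res.mean_pa < 0

    def test_zero_variance_differences_undefined(self):
        res = magnitude_paired_t([10, 11, 12], [10, 11, 12])
        assert math.isnan(res.t) and math.isnan(res.p)

    def test_symmetric_pairs_counted_in_df(self):
        # pairs with d = 0 stay in: N = 4 -> df = 3
        res = magnitude_paired_t([10, 10, 10, 10], [10, 10, 10, 12])
        assert res.df == 3


class TestBonferroni:
    @pytest.mark.parametrize(
        "n, alpha, expected", [(9, 0.05, 0.006), (1, 0.05, 0.05), (2, 0.10, 0.05)]
    )
    def test_threshold(self, n, alpha, expected):
        assert round(bonferroni_alpha(n, alpha), 3) == expected


class TestSummarize:
    def test_counts_drive_frequency_statistic(self):
        # 22 left-larger vs 44 right-larger individuals, 6 symmetric
        pairs = [(10.2, 10.0)] * 22 + [(10.0, 10.2)] * 44 + [(10.0, 10.0)] * 6
        s = summarize_taxon(make_sample(pairs))
        assert (s.n, s.n_left_larger, s.n_right_larger, s.n_symmetric) == (72, 22, 44, 6)
        assert round(s.frequency.chi2, 2) == 3.12
        assert s.magnitude.df == 71

    def test_significance_marks_and_bias(self):
        pairs = [(10.0, 10.4)] * 51 + [(10.4, 10.0)] * 23
        s = summarize_taxon(make_sample(pairs))
        assert round(s.frequency.chi2, 2) == 4.74
        assert s.freq_significant_raw and s.freq_bias == "right"
        assert not s.freq_significant_corrected  # .030 > 0.05/9

    def test_fully_symmetric_sample_errors(self):
        with pytest.raises(ValueError):
            summarize_taxon(make_sample([(10.0, 10.0)] * 10))

    def test_pa_based_t_variant(self):
        pairs = [(10.0, 10.5), (10.0, 10.3), (10.2, 10.0), (10.0, 10.1)]
        s = summarize_taxon(make_sample(pairs), paired_on="pa")
        pa = [r.percent_asymmetry for r in make_sample(pairs).records]
        ref = one_sample_pa_t(pa)
        assert s.magnitude.t == pytest.approx(ref.t)


class TestFormatP:
    @pytest.mark.parametrize(
        "p, expected", [(0.191, ".191"), (1.0, "1.000"), (0.0004, ".000"), (float("nan"), "NA")]
    )
    def test_report_style(self, p, expected):
        assert format_p(p) == expected
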