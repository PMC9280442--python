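"""Frequency and magnitude tests of directional asymmetry, per taxon x element.

Two complementary questions are asked of each sample:

* **Frequency**: among informative individuals (symmetric ones excluded), do
  left-larger and right-larger counts deviate from 50:50?  The default
  statistic is a 1-df chi square computed on the 2x2 table whose first row is
  the observed counts and whose second row is the 50:50 expectation
  ``(E, E)``, ``E = (n_left + n_right)/2``, with expected cell counts from the
  table margins and a Yates continuity correction — each cell contributes
  ``max(|O - E_hat| - 0.5, 0)^2 / E_hat``.  This observed-vs-expected
  construction (the one R's ``chisq.test`` applies to a 2x2 matrix) is
  deliberately NOT the plain one-sample goodness-of-fit, which is offered as a
  labelled alternative alongside an exact two-sided binomial test.
* **Magnitude**: across all paired individuals (including symmetric ones), is
  the mean right-minus-left difference nonzero?  A two-tailed paired t-test on
  the raw lengths, df = N - 1; a variant on the per-individual PA values is
  available.  Positive t means right-larger on average.

Significance is marked both at the raw alpha and at a Bonferroni-corrected
alpha (default: the family alpha split over 9 tests per statistical approach,
0.05/9 ~ 0.006).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .asymmetry import LEFT_LARGER, RIGHT_LARGER, TaxonTraitSample, percent_asymmetry

__all__ = [
    "FrequencyTestResult",
    "MagnitudeTestResult",
    "TaxonSummary",
    "frequency_chi_square",
    "magnitude_paired_t",
    "one_sample_pa_t",
    "bonferroni_alpha",
    "summarize_taxon",
    "format_p",
]


@dataclass(frozen=True)
class FrequencyTestResult:
    n_left_larger: int
    n_right_larger: int
    expected_per_side: float  # may be half-integral
    chi2: float               # nan for the exact binomial method
    df: int
    p: float
    method: str = "yates"


@dataclass(frozen=True)
class MagnitudeTestResult:
    t: float          # nan when sd of the paired differences is zero
    df: int
    p: float
    mean_pa: float
    sd_pa: float
    mean_diff: float  # mean(right - left), mm
    n: int


def frequency_chi_square(
    n_left: int, n_right: int, method: str = "yates"
) -> FrequencyTestResult:
    """Test left- vs right-larger counts against 50:50.

    ``method``:
      * ``"yates"`` (default) — continuity-corrected chi square on the 2x2
        observed-vs-expected table described in the module docstring;
      * ``"uncorrected"`` — plain one-sample goodness-of-fit
        ``sum((O - E)^2 / E)`` over the two observed counts;
      * ``"binomial"`` — exact two-sided binomial test (statistic reported as
        NaN, only the p-value is defined).

    With the default method the statistic is zero whenever the counts differ
    by at most one, and is symmetric in its two arguments.
    """
    if n_left < 0 or n_right < 0:
        raise ValueError("counts must be non-negative")
    total = n_left + n_right
    if total == 0:
        raise ValueError("frequency test undefined: no informative (asymmetric) individuals")
    expected = total / 2.0

    if method == "yates":
        observed = np.array([[n_left, n_right], [expected, expected]], dtype=float)
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        ehat = row * col / observed.sum()
        dev = np.maximum(np.abs(observed - ehat) - 0.5, 0.0)
        chi2 = float((dev**2 / ehat).sum())
        p = float(stats.chi2.sf(chi2, 1))
    elif method == "uncorrected":
        chi2 = float((n_left - expected) ** 2 / expected + (n_right - expected) ** 2 / expected)
        p = float(stats.chi2.sf(chi2, 1))
    elif method == "binomial":
        chi2 = math.nan
        p = float(stats.binomtest(n_left, total, 0.5).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    return FrequencyTestResult(
        n_left_larger=n_left,
        n_right_larger=n_right,
        expected_per_side=expected,
        chi2=chi2,
        df=1,
        p=p,
        method=method,
    )


def magnitude_paired_t(
    left_lengths: Sequence[float], right_lengths: Sequence[float]
) -> MagnitudeTestResult:
    """Two-tailed paired t-test of right vs left lengths (mm).

    Pairs with zero difference are retained (they carry information that the
    sides are equal), so df = N - 1 with N the full pair count.  When the
    paired differences have zero SD the t statistic is undefined and reported
    as NaN.  Also reports the mean and SD of the per-individual PA values.
    """
    left = np.asarray(left_lengths, dtype=float)
    right = np.asarray(right_lengths, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("left and right must be 1D sequences of equal length")
    n = left.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = right - left
    sd = float(d.std(ddof=1))
    if sd == 0:
        t = p = math.nan
    else:
        t = float(d.mean() / (sd / math.sqrt(n)))
        p = float(2 * stats.t.sf(abs(t), n - 1))
    pa = np.array([percent_asymmetry(l, r) for l, r in zip(left, right)])
    return MagnitudeTestResult(
        t=t,
        df=n - 1,
        p=p,
        mean_pa=float(pa.mean()),
        sd_pa=float(pa.std(ddof=1)),
        mean_diff=float(d.mean()),
        n=n,
    )


def one_sample_pa_t(pa_values: Sequence[float]) -> MagnitudeTestResult:
    """Magnitude test variant: one-sample t of the PA values against zero."""
    pa = np.asarray(pa_values, dtype=float)
    n = pa.size
    if n < 2:
        raise ValueError("t-test needs at least 2 values")
    sd = float(pa.std(ddof=1))
    if sd == 0:
        t = p = math.nan
    else:
        t = float(pa.mean() / (sd / math.sqrt(n)))
        p = float(2 * stats.t.sf(abs(t), n - 1))
    return MagnitudeTestResult(
        t=t, df=n - 1, p=p, mean_pa=float(pa.mean()), sd_pa=sd, mean_diff=math.nan, n=n
    )


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must be in (0, 1)")
    return family_alpha / n_tests


@dataclass(frozen=True)
class TaxonSummary:
    """One summary row: both tests plus significance marks for a taxon x element."""

    taxon: str
    element: str
    n: int
    n_left_larger: int
    n_right_larger: int
    n_symmetric: int
    frequency: FrequencyTestResult
    magnitude: MagnitudeTestResult
    alpha: float
    bonferroni: float
    freq_significant_raw: bool
    freq_significant_corrected: bool
    freq_bias: str | None   # "left"/"right" when significant at raw alpha
    mag_significant_raw: bool
    mag_significant_corrected: bool
    mag_bias: str | None


def summarize_taxon(
    sample: TaxonTraitSample,
    family_alpha: float = 0.05,
    n_tests: int = 9,
    paired_on: str = "lengths",
    frequency_method: str = "yates",
) -> TaxonSummary:
    """Run both tests on a filtered sample and attach significance marks.

    ``paired_on`` selects the magnitude test input: ``"lengths"`` (default,
    paired t on raw left/right lengths) or ``"pa"`` (one-sample t of PA against
    zero).  Errors from degenerate samples (e.g. every individual symmetric)
    propagate.
    """
    freq = frequency_chi_square(sample.n_left_larger, sample.n_right_larger, method=frequency_method)

    paired = [r for r in sample.active_records if r.complete]
    if paired_on == "lengths":
        mag = magnitude_paired_t(
            [r.left_length for r in paired], [r.right_length for r in paired]
        )
    elif paired_on == "pa":
        mag = one_sample_pa_t([r.percent_asymmetry for r in paired])
    else:
        raise ValueError(f"unknown paired_on {paired_on!r}")

    alpha = family_alpha
    bonf = bonferroni_alpha(n_tests, family_alpha)

    freq_raw = freq.p < alpha
    freq_dir = LEFT_LARGER if sample.n_left_larger > sample.n_right_larger else RIGHT_LARGER
    mag_raw = (not math.isnan(mag.t)) and mag.p < alpha
    mag_dir = LEFT_LARGER if mag.mean_pa < 0 else RIGHT_LARGER

    return TaxonSummary(
        taxon=sample.taxon,
        element=sample.element,
        n=sample.n_total,
        n_left_larger=sample.n_left_larger,
        n_right_larger=sample.n_right_larger,
        n_symmetric=sample.n_symmetric,
        frequency=freq,
        magnitude=mag,
        alpha=alpha,
        bonferroni=bonf,
        freq_significant_raw=freq_raw,
        freq_significant_corrected=freq.p < bonf,
        freq_bias=("left" if freq_dir == LEFT_LARGER else "right") if freq_raw else None,
        mag_significant_raw=mag_raw,
        mag_significant_corrected=mag_raw and mag.p < bonf,
        mag_bias=("left" if mag_dir == LEFT_LARGER else "right") if mag_raw else None,
    )


def format_p(p: float, digits: int = 3) -> str:
    """Report-style p-value: 3 dp, leading zero stripped ('.191', '1.000')."""
    if math.isnan(p):
        return "NA"
    s = f"{p:.{digits}f}"
    return s[1:] if s.startswith("0.") else s
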