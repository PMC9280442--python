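"""Chi-square power analysis for the frequency test.

For a 1-df chi-square test of left/right frequencies, power at Cohen's effect
size ``w`` and sample size ``N`` is governed by the noncentral chi-square
distribution with noncentrality ``lambda = N * w**2``:

    power = P[ X > c ],   X ~ ncx2(df, lambda),
    c = (1 - alpha) quantile of the central chi2(df).

At ``w = 0`` the alternative equals the null and power equals alpha exactly.
``N`` here is the count of informative (asymmetric) individuals — the same N
that enters the frequency test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PowerQuery", "chi_square_power", "required_sample_size", "power_table"]


@dataclass(frozen=True)
class PowerQuery:
    """One power evaluation point: effect size w, sample size N, df, alpha."""

    w: float
    n: int
    df: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("effect size w must be >= 0")
        if self.n < 1:
            raise ValueError("sample size N must be >= 1")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def noncentrality(self) -> float:
        return self.n * self.w**2

    @property
    def power(self) -> float:
        return chi_square_power(self.w, self.n, self.df, self.alpha)


def chi_square_power(w: float, n: int, df: int = 1, alpha: float = 0.05) -> float:
    """Power of the chi-square test at effect size ``w`` and sample size ``n``."""
    q = PowerQuery(w=w, n=n, df=df, alpha=alpha)  # validates
    lam = q.noncentrality
    if lam == 0:
        return alpha
    crit = stats.chi2.ppf(1 - alpha, df)
    return float(stats.ncx2.sf(crit, df, lam))


def required_sample_size(
    w: float, df: int = 1, alpha: float = 0.05, target_power: float = 0.5
) -> int:
    """Smallest integer N with power strictly above ``target_power``.

    The returned N satisfies ``power(N) > target_power`` and
    ``power(N - 1) <= target_power`` (or N == 1).  Power is monotone increasing
    in N for ``w > 0``, so a doubling bracket plus integer bisection suffices.
    """
    if w <= 0:
        raise ValueError("required sample size is unbounded for w <= 0")
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")

    if chi_square_power(w, 1, df, alpha) > target_power:
        return 1
    lo, hi = 1, 2
    while chi_square_power(w, hi, df, alpha) <= target_power:
        lo, hi = hi, hi * 2
        if hi > 10**9:
            raise RuntimeError("sample size search did not converge")
    # invariant: power(lo) <= target < power(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if chi_square_power(w, mid, df, alpha) > target_power:
            hi = mid
        else:
            lo = mid
    return hi


DEFAULT_W_GRID = tuple(np.round(np.arange(0.0, 0.51, 0.05), 2))
DEFAULT_N_GRID = tuple(range(10, 201, 10))


def power_table(
    w_grid: Sequence[float] | None = None,
    n_grid: Sequence[int] | None = None,
    df: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power for each (w, N) pair: rows indexed by w, columns by N.

    Defaults cover effect sizes 0.0-0.5 in steps of 0.05 at alpha = 0.05,
    df = 1 (the planning grid for the frequency test).
    """
    ws = list(DEFAULT_W_GRID if w_grid is None else w_grid)
    ns = list(DEFAULT_N_GRID if n_grid is None else n_grid)
    if not ws or not ns:
        raise ValueError("grids must be non-empty")
    data = [[chi_square_power(w, n, df, alpha) for n in ns] for w in ws]
    table = pd.DataFrame(data, index=pd.Index(ws, name="w"), columns=pd.Index(ns, name="N"))
    return table
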