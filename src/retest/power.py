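"""Sample-size computation from Cohen's d, and d estimation from a table.

The core routine inverts the exact power function of the two-sample
t-test: at n per group (allocation ratio r gives n2 = r * n1) the test
statistic under the alternative follows a noncentral t with
df = n1 + n2 - 2 and noncentrality d * sqrt(n1 n2 / (n1 + n2)); the
smallest integer n reaching the target power is found by bracketed
search. For the Wilcoxon-Mann-Whitney alternative the t-test n is
inflated by the asymptotic relative efficiency 3/pi of the rank test
under a normal parent (so the rank-test n is the t-test n divided by
3/pi, then ceiled).

A reliability context note: in a test-retest design the "effect" between
sessions is technical noise, so the standardized session difference d is
small precisely when reliability is high — and the n needed to *detect*
that technical difference is then enormous. That inverse relationship is
the point of tabulating d and n next to the ICC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .feature_io import FeatureTable

#: asymptotic relative efficiency of the Wilcoxon test vs the t-test
#: under a normal parent distribution
ARE_NORMAL = 3.0 / math.pi

N_MAX = 10_000_000  # overflow guard for absurdly small d


@dataclass
class PowerQuery:
    """One sample-size question: effect size, error rates, test family."""

    d: float
    alpha: float = 0.05
    power: float = 0.8
    tails: int = 2
    test: str = "two_sample_t"  # or "wilcoxon_are"
    allocation: float = 1.0  # n2 = allocation * n1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if self.d <= 0.0:
            raise ValueError("d must be positive")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.test not in ("two_sample_t", "wilcoxon_are"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.allocation <= 0.0:
            raise ValueError("allocation ratio must be positive")


def two_sample_t_power(
    d: float, n1: int, n2: int | None = None, alpha: float = 0.05, tails: int = 2
) -> float:
    """Exact power of the two-sample t-test via the noncentral t."""
    n2 = n1 if n2 is None else n2
    df = n1 + n2 - 2
    if df < 1:
        return 0.0
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    if tails == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(
            1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        )
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp))


def _power_at(query: PowerQuery, n1: int) -> float:
    n2 = max(2, math.ceil(query.allocation * n1))
    return two_sample_t_power(query.d, n1, n2, query.alpha, query.tails)


def required_n(query: PowerQuery) -> tuple[int, int]:
    """Smallest n per group reaching the target power; returns (n1, n_total).

    The t-test n is found by doubling until the power is reached, then
    bisection — so the returned n attains the target and n - 1 does not.
    For ``wilcoxon_are`` the t-test n is divided by the ARE 3/pi and
    ceiled.
    """
    lo, hi = 2, 2
    while _power_at(query, hi) < query.power:
        lo, hi = hi, hi * 2
        if hi > N_MAX:
            raise OverflowError(
                f"required n exceeds {N_MAX:,}: d = {query.d} is too small"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _power_at(query, mid) >= query.power:
            hi = mid
        else:
            lo = mid
    n1 = hi
    if query.test == "wilcoxon_are":
        n1 = math.ceil(n1 / ARE_NORMAL)
    n2 = max(2, math.ceil(query.allocation * n1))
    return n1, n1 + n2


def cohens_d_between_sessions(
    table: FeatureTable, feature: int | str | None = None, paired: bool = False
) -> float | np.ndarray:
    """Standardized session difference, per feature or for one feature.

    Two-sample framing (default): |mean(test) - mean(retest)| divided by
    the equally-weighted pooled SD sqrt((s_test^2 + s_retest^2)/2).
    ``paired=True`` instead standardises by the SD of the within-subject
    differences. Both framings are scale-invariant.
    """
    test, retest = table.session(0), table.session(1)
    if feature is not None:
        r = (
            table.feature_names.index(feature)
            if isinstance(feature, str)
            else int(feature)
        )
        test, retest = test[:, [r]], retest[:, [r]]
    if paired:
        diff = test - retest
        sd = diff.std(axis=0, ddof=1)
    else:
        sd = np.sqrt(
            (test.var(axis=0, ddof=1) + retest.var(axis=0, ddof=1)) / 2.0
        )
    if np.any(sd == 0.0):
        raise ValueError("zero pooled SD: d undefined")
    d = np.abs(test.mean(axis=0) - retest.mean(axis=0)) / sd
    return float(d[0]) if feature is not None else d
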