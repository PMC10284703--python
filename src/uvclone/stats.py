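"""Exact tests shared across the pipeline.

The two-sided Fisher test uses the minimum-likelihood convention (sum the
probabilities of all tables, with the observed margins, whose probability does
not exceed that of the observed table). The two-sided binomial test doubles
the smaller exact tail and caps at one; the conventions differ in general and
each function documents its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float

    def __iter__(self):
        return iter((self.odds_ratio, self.p_value))


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The p-value sums hypergeometric probabilities of tables at the observed
    margins that are no more likely than the observed one (with a 1 + 1e-7
    relative guard against floating-point ties). The odds ratio is the sample
    odds ratio ``(a*d)/(b*c)`` (``inf`` when ``b*c == 0`` and ``a*d > 0``).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    (a, b), (c, d) = t
    n = t.sum()
    if n == 0:
        raise ValueError("table must have at least one positive margin")
    r1, c1 = a + b, a + c
    # support of the a-cell given fixed margins
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(float(odds), p)


def binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test by doubling the smaller tail, capped at 1."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if n == 0:
        return 1.0
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str


def rank_sum_test(a, b, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses exact enumeration when both groups have fewer than 20 observations
    and there are no ties, and the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size < 20 and b.size < 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), method)
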