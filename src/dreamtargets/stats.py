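"""Shared statistical tests.

Thin, contract-checked wrappers around scipy/statsmodels covering the tests
used throughout the pipeline: hypergeometric overlap enrichment, Fisher's
exact test on 2x2 tables, the Wilcoxon rank-sum test, Welch's t, and
Benjamini-Hochberg FDR control.  All combinatorics are evaluated in log
space internally (scipy), so p-values far below float underflow of naive
factorial ratios (e.g. 1e-76) remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "hypergeom_upper_tail",
    "fisher_exact_two_sided",
    "wilcoxon_rank_sum",
    "welch_t",
    "bh_adjust",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; all non-negative, at least one positive."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise ValueError(f"2x2 table cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("2x2 table is all zero")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: number of successes in the universe, n: draws,
    k: observed successes among the draws.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K, n)=min({K},{n})]")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_exact_two_sided(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test.

    Returns (odds_ratio, p).  The two-sided p sums the probabilities of all
    tables with the observed margins whose pmf is <= the observed pmf.  The
    odds ratio is the sample estimate a*d / (b*c); infinite when b*c == 0
    and a*d > 0, and nan for fully degenerate tables.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        oddsratio = math.nan if a * d == 0 else math.inf
    else:
        oddsratio = (a * d) / (b * c)
    # degenerate margin: only one table possible
    if min(a + b, c + d, a + c, b + d) == 0:
        return oddsratio, 1.0
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return oddsratio, float(min(p, 1.0))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (U, p).

    Exact permutation null when min(n) <= 10 and there are no ties across
    the pooled sample; otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, p_two_sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires n >= 2 in each sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        # degenerate: no within-group variability
        if x.mean() == y.mean():
            return 0.0, math.nan, 1.0
        return math.inf if x.mean() > y.mean() else -math.inf, math.nan, 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    se2 = vx / x.size + vy / y.size
    df = se2**2 / ((vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
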