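"""Shared statistical primitives.

The exact Mann-Whitney U test is implemented here (rank-sum distribution by
dynamic programming over doubled mid-ranks, which keeps tied ranks integral)
because small two-group comparisons throughout the pipeline require exact
p-values.  Benjamini-Hochberg adjustment is delegated to statsmodels.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["mannwhitney_p", "exact_mannwhitney_p", "bh_adjust", "round2"]

# combined sample size at or below which the exact null distribution is used
EXACT_N_MAX = 25


def _rank2(pooled: np.ndarray) -> np.ndarray:
    """Mid-ranks times two (always integers, even with ties)."""
    r2 = 2.0 * sps.rankdata(pooled)
    out = np.rint(r2).astype(np.int64)
    if not np.allclose(r2, out):  # pragma: no cover - mid-ranks are k/2
        raise AssertionError("doubled mid-ranks must be integral")
    return out


def _ranksum_null_counts(ranks2: np.ndarray, n1: int) -> np.ndarray:
    """Number of size-``n1`` subsets of ``ranks2`` per doubled rank-sum.

    dp[j, s] counts subsets of size j summing to s; equivalent to full
    enumeration of the C(N, n1) group labelings.
    """
    total = int(ranks2.sum())
    dp = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    return dp[n1]


def exact_mannwhitney_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p-value (2*min(tail), capped at 1).

    Ties are handled exactly: the permutation distribution of the mid-rank
    sum is computed for the observed pooled data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks2 = _rank2(pooled)
    w_obs = int(ranks2[:n1].sum())
    counts = _ranksum_null_counts(ranks2, n1)
    n_total = counts.sum()
    lo = counts[: w_obs + 1].sum() / n_total
    hi = counts[w_obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(lo, hi)))


def _approx_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def mannwhitney_p(x, y, exact: bool | None = None) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact by full permutation-distribution computation when the combined
    sample size is at most ``EXACT_N_MAX`` (or when ``exact=True``),
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if exact is None:
        exact = (len(x) + len(y)) <= EXACT_N_MAX
    if exact:
        return exact_mannwhitney_p(x, y)
    return _approx_mannwhitney_p(x, y)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def round2(value: float) -> float:
    """Display rounding to 2 decimals, half away from zero.

    The value is first quantized to 8 decimals (half-even) to shed binary
    floating-point representation error, so e.g. a mean whose exact decimal
    value is 96.515 rounds to 96.52 rather than 96.51.
    """
    d = Decimal(repr(float(value))).quantize(Decimal("1e-8"), ROUND_HALF_EVEN)
    return float(d.quantize(Decimal("0.01"), ROUND_HALF_UP))
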