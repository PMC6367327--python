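"""Shared statistical engines.

Small-sample paths are exact (enumeration of the permutation null); large
samples fall back to the standard asymptotic approximations. The chi-squared
statistic is computed directly from the contingency formula so that the
degenerate zero-margin case has a controlled (chi2 = 0, p = 1) outcome.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "pearson_chi2_2x2",
    "rank_sum_test",
    "ks_test",
    "pearson_correlation",
]

# exact rank-sum enumeration is used while C(n1+n2, n1) stays below this
_EXACT_ENUMERATION_LIMIT = 20_000


def pearson_chi2_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table, without continuity correction.

    Parameters
    ----------
    table : 2x2 array-like of non-negative counts, rows = groups,
        columns = categories.

    Returns
    -------
    (chi2, p) : the statistic and the upper-tail probability on 1 df.
        A table with a zero row or column margin carries no information and
        returns (0.0, 1.0).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if total == 0 or (row == 0).any() or (col == 0).any():
        return 0.0, 1.0
    expected = np.outer(row, col) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def _rank_sum_exact_p(ranks: np.ndarray, n1: int, observed: float) -> float:
    """Two-sided exact p for the rank-sum statistic by enumeration.

    Enumerates every choice of n1 positions out of the pooled midranks and
    counts assignments at least as far from the null mean as the observed
    rank sum. Ties are handled exactly because midranks are enumerated as-is.
    """
    n = ranks.size
    mu = n1 * (n + 1) / 2.0
    dev = abs(observed - mu) - 1e-9  # guard float error in midrank sums
    hits = 0
    count = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= dev:
            hits += 1
        count += 1
    return hits / count


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the permutation null (tie-aware, via midranks) when
    the number of assignments C(n1+n2, n1) is at most 20000; otherwise the
    normal approximation with tie correction and no continuity correction,
    so identical samples yield p = 1.

    Returns
    -------
    (W, p) : rank-sum of `x` over the pooled sample, and the two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if math.comb(n, n1) <= _EXACT_ENUMERATION_LIMIT:
        return w, _rank_sum_exact_p(ranks, n1, w)
    mu = n1 * (n + 1) / 2.0
    # tie correction over groups of equal pooled values
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all pooled values identical
        return w, 1.0
    z = (w - mu) / math.sqrt(sigma2)
    return w, float(2.0 * sps.norm.sf(abs(z)))


def ks_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample, two-sided Kolmogorov-Smirnov test.

    Uses the exact null distribution below a combined sample size of 35 and
    the asymptotic distribution above.

    Returns
    -------
    (D, p) : the KS statistic and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if x.size + y.size < 35 else "asymp"
    res = sps.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float] | None:
    """Pearson product-moment correlation on complete pairs.

    Pairs with a missing (NaN) member are dropped; returns None when fewer
    than 3 complete pairs remain or a vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
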