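"""Statistical primitives shared across the discordance analyses.

Exact binomial intervals, simultaneous proportion comparisons, pairwise
mean-difference intervals for unequal group sizes, rank-sum tests, odds
ratios, percentile bootstrap intervals and McNemar's test for paired
binary outcomes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExactCI",
    "OddsRatioResult",
    "clopper_pearson",
    "marascuilo",
    "dtk_pairwise",
    "wilcoxon_rank_sum",
    "odds_ratio",
    "bootstrap_ci",
    "mcnemar",
]

#: combined-sample-size ceiling for the exact rank-sum branch
WILCOXON_EXACT_MAX_N = 12
#: discordant-pair ceiling (inclusive) for the exact McNemar branch
MCNEMAR_EXACT_MAX = 25


@dataclass(frozen=True)
class ExactCI:
    """Exact two-sided binomial confidence interval for ``x`` successes in ``n``."""

    x: int
    n: int
    level: float
    low: float
    high: float

    @property
    def estimate(self) -> float:
        return self.x / self.n


def clopper_pearson(x: int, n: int, level: float = 0.95) -> ExactCI:
    """Two-sided exact (beta-quantile) confidence interval for a proportion.

    Parameters
    ----------
    x : number of successes, ``0 <= x <= n``.
    n : number of trials, ``n > 0``.
    level : two-sided confidence level.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return ExactCI(x=int(x), n=int(n), level=level, low=low, high=high)


def marascuilo(
    proportions: Sequence[float], ns: Sequence[int], alpha: float = 0.05
) -> pd.DataFrame:
    """Simultaneous pairwise comparison of several proportions.

    Each pair (i, j) is flagged significant when ``|p_i - p_j|`` exceeds the
    chi-square based critical range
    ``sqrt(chi2_{1-alpha, k-1}) * sqrt(p_i q_i / n_i + p_j q_j / n_j)``.

    Returns a data frame with one row per pair.
    """
    p = np.asarray(proportions, dtype=float)
    n = np.asarray(ns, dtype=float)
    if p.size < 2 or p.size != n.size:
        raise ValueError("need >= 2 groups with matching sample sizes")
    if np.any(n <= 0):
        raise ValueError("all group sizes must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    k = p.size
    chi_crit = math.sqrt(sps.chi2.ppf(1 - alpha, k - 1))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(p[i] - p[j])
        critical = chi_crit * math.sqrt(
            p[i] * (1 - p[i]) / n[i] + p[j] * (1 - p[j]) / n[j]
        )
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "abs_diff": diff,
                "critical_range": critical,
                "significant": diff > critical,
            }
        )
    return pd.DataFrame(rows)


def dtk_pairwise(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise mean-difference intervals for unequal sample sizes/variances.

    Dunnett's C procedure: the studentized-range quantile for each pair is a
    variance-weighted combination of the per-group quantiles, and the margin
    uses the unpooled standard error.  Valid under unequal n and unequal
    variances; reduces to a single comparison for two groups.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for g in samples:
        if g.size < 2:
            raise ValueError("each group needs >= 2 observations")
    k = len(samples)
    means = [g.mean() for g in samples]
    variances = [g.var(ddof=1) for g in samples]
    ns = [g.size for g in samples]
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        vi, vj = variances[i] / ns[i], variances[j] / ns[j]
        se2 = vi + vj
        if se2 == 0:
            q = 0.0
        else:
            qi = sps.studentized_range.ppf(1 - alpha, k, ns[i] - 1)
            qj = sps.studentized_range.ppf(1 - alpha, k, ns[j] - 1)
            q = (qi * vi + qj * vj) / se2
        margin = q * math.sqrt(se2 / 2.0)
        diff = means[i] - means[j]
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "mean_diff": diff,
                "ci_low": diff - margin,
                "ci_high": diff + margin,
                "significant": (diff - margin > 0) or (diff + margin < 0),
            }
        )
    return pd.DataFrame(rows)


def _rank_sum_exact_p(ranks: np.ndarray, na: int, observed: float) -> float:
    """Two-sided exact p by enumeration of all rank assignments."""
    n = ranks.size
    sums = np.array(
        [sum(c) for c in itertools.combinations(ranks, na)], dtype=float
    )
    mu = sums.mean()
    dev = abs(observed - mu)
    # two-sided: doubling the smaller tail, capped at 1
    lo = np.mean(sums <= mu - dev + 1e-12)
    hi = np.mean(sums >= mu + dev - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample rank-sum test (two-sided).

    Exact enumeration over all rank assignments when the combined sample size
    is <= 12; otherwise the normal approximation with tie correction and a
    0.5 continuity correction.  Returns ``(rank_sum_of_a, p_value)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na, nb = a.size, b.size
    n = na + nb
    w = float(ranks[:na].sum())
    if np.unique(pooled).size == 1:
        return w, 1.0
    if n <= WILCOXON_EXACT_MAX_N:
        return w, _rank_sum_exact_p(ranks, na, w)
    mu = na * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    return w, float(2 * sps.norm.sf(max(z, 0.0)))


@dataclass(frozen=True)
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool  # Haldane-Anscombe 0.5 applied to every cell


def odds_ratio(
    a: int, b: int, c: int, d: int, level: float = 0.95
) -> OddsRatioResult:
    """Odds ratio for the 2x2 table ``[[a, b], [c, d]]``.

    Woolf log-normal confidence interval and a Wald p-value on the log scale.
    A 0.5 correction is added to every cell when any cell is zero (flagged in
    the result).  Two zero cells sharing a row or column leave the odds ratio
    undefined and yield NaNs.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    degenerate = (a == 0 and b == 0) or (c == 0 and d == 0) or (
        a == 0 and c == 0
    ) or (b == 0 and d == 0)
    if degenerate:
        return OddsRatioResult(math.nan, math.nan, math.nan, math.nan, False)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    orr = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    log_or = math.log(orr)
    p = float(2 * sps.norm.sf(abs(log_or) / se))
    return OddsRatioResult(
        oddsratio=float(orr),
        ci_low=float(math.exp(log_or - z * se)),
        ci_high=float(math.exp(log_or + z * se)),
        p=p,
        corrected=corrected,
    )


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for ``statistic(values)``.

    Resamples on which the statistic is undefined (NaN or raising) are
    redrawn, up to ``max_retries`` times each.
    """
    data = np.asarray(values, dtype=float)
    if data.size < 2:
        raise ValueError("need >= 2 observations")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    alpha = 1.0 - level
    reps = np.empty(n_boot)
    for i in range(n_boot):
        for attempt in range(max_retries + 1):
            sample = rng.choice(data, size=data.size, replace=True)
            try:
                val = float(statistic(sample))
            except (ValueError, ZeroDivisionError, FloatingPointError):
                val = math.nan
            if not math.isnan(val):
                reps[i] = val
                break
        else:
            raise RuntimeError("statistic undefined on all resamples")
    return (
        float(np.quantile(reps, alpha / 2)),
        float(np.quantile(reps, 1 - alpha / 2)),
    )


def mcnemar(b: int, c: int) -> tuple[float, float]:
    """McNemar's test on the discordant cells of a paired 2x2 table.

    Exact binomial (tail doubling) for ``b + c <= 25``, otherwise chi-square
    with continuity correction.  Returns ``(statistic, p)``; the statistic is
    ``min(b, c)`` on the exact branch.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        return 0.0, 1.0
    if m <= MCNEMAR_EXACT_MAX:
        k = min(b, c)
        p = min(1.0, 2.0 * float(sps.binom.cdf(k, m, 0.5)))
        return float(k), p
    stat = (abs(b - c) - 1) ** 2 / m
    return float(stat), float(sps.chi2.sf(stat, 1))
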