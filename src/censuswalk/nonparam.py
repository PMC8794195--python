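"""Nonparametric toolbox: runs test, Hodges–Lehmann, Theil, JB, Smirnov.

Hospital operating series are integer-valued, tie-heavy and decidedly
non-Gaussian, and derived ratios (per-day mean length of stay) can follow
heavy-tailed laws without moments — so every summary here is rank- or
order-statistic-based.  The runs-about-the-median test is the primary
dependence screen: an i.i.d. sequence of n points produces about n/2 + 1
runs, while a random walk or trend produces far fewer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RunsResult",
    "TheilFit",
    "runs_test",
    "hl_median_ci",
    "theil_regression",
    "jarque_bera",
    "smirnov_two_sample",
]

#: sample-size bound below which the exact runs distribution is used
EXACT_RUNS_LIMIT = 40


@dataclass(frozen=True)
class RunsResult:
    """Outcome of the Wald–Wolfowitz runs-about-the-median test.

    ``p_lower`` is P(R ≤ observed) — the tail sensitive to walks and trends,
    which produce too few runs.  Points equal to the median are discarded
    before counting.
    """

    n_used: int
    n_above: int
    n_below: int
    n_runs: int
    p_lower: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


def runs_pmf(n_above: int, n_below: int) -> np.ndarray:
    """Exact null pmf of the run count for a two-symbol sequence.

    Index r of the returned array is P(R = r), from the classical
    combinatorial count of arrangements of ``n_above`` + ``n_below`` symbols
    forming exactly r maximal runs.
    """
    m, n = n_above, n_below
    total = math.comb(m + n, m)
    pmf = np.zeros(m + n + 1)
    for r in range(2, m + n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * math.comb(m - 1, k - 1) * math.comb(n - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = math.comb(m - 1, k - 1) * math.comb(n - 1, k) + math.comb(
                m - 1, k
            ) * math.comb(n - 1, k - 1)
        pmf[r] = ways / total
    return pmf


def runs_test(ys) -> RunsResult:
    """Runs-about-the-median test for serial dependence.

    Exact combinatorial tail probabilities for up to 40 usable points, a
    continuity-corrected normal approximation beyond.
    """
    ys = np.asarray(ys, dtype=float)
    if np.isnan(ys).any():
        raise ValueError("runs_test requires a series without missing values")
    med = float(np.median(ys))
    kept = ys[ys != med]
    n_used = len(kept)
    if n_used == 0:
        raise ValueError("all values tie the median; no runs to count")
    above = kept > med
    n_above = int(above.sum())
    n_below = n_used - n_above
    if n_above == 0 or n_below == 0:
        raise ValueError("degenerate sequence: all values on one side of the median")
    n_runs = 1 + int(np.count_nonzero(above[1:] != above[:-1]))

    if n_used <= EXACT_RUNS_LIMIT:
        pmf = runs_pmf(n_above, n_below)
        p_lower = float(pmf[: n_runs + 1].sum())
        p_upper = float(pmf[n_runs:].sum())
        method = "exact"
    else:
        m, n = n_above, n_below
        mean = 1.0 + 2.0 * m * n / (m + n)
        var = (
            2.0 * m * n * (2.0 * m * n - m - n)
            / ((m + n) ** 2 * (m + n - 1.0))
        )
        sd = math.sqrt(var)
        p_lower = float(stats.norm.cdf((n_runs + 0.5 - mean) / sd))
        p_upper = float(stats.norm.sf((n_runs - 0.5 - mean) / sd))
        method = "normal_approx"
    p_two = min(1.0, 2.0 * min(p_lower, p_upper))
    return RunsResult(
        n_used=n_used,
        n_above=n_above,
        n_below=n_below,
        n_runs=n_runs,
        p_lower=min(p_lower, 1.0),
        p_two_sided=p_two,
        method=method,
    )


def _signed_rank_cdf(n: int) -> np.ndarray:
    """Null distribution of the Wilcoxon signed-rank statistic by convolution."""
    counts = np.array([1.0])
    for rank in range(1, n + 1):
        new = np.zeros(len(counts) + rank)
        new[: len(counts)] += counts
        new[rank:] += counts
        counts = new
    return np.cumsum(counts) / counts.sum()


def hl_median_ci(ys, conf: float = 0.95) -> tuple[float, float, float]:
    """Hodges–Lehmann location estimate with a rank-based confidence interval.

    The estimate is the median of all Walsh averages (xᵢ + xⱼ)/2 with i ≤ j.
    The interval takes the k-th smallest and k-th largest Walsh average, with
    k from the Wilcoxon signed-rank critical value (exact null distribution
    for small samples, normal approximation beyond).
    """
    ys = np.asarray(ys, dtype=float)
    n = len(ys)
    if n == 0:
        raise ValueError("empty sample")
    iu, ju = np.triu_indices(n)
    walsh = np.sort((ys[iu] + ys[ju]) / 2.0)
    estimate = float(np.median(walsh))
    if n == 1:
        return estimate, estimate, estimate
    alpha = 1.0 - conf
    n_walsh = len(walsh)
    if n <= 50:
        # k_crit = max{w : P(W <= w) <= α/2}; CI endpoints are the
        # (k_crit + 1)-th smallest and largest Walsh averages.
        cdf = _signed_rank_cdf(n)
        k_crit = int(np.searchsorted(cdf, alpha / 2.0, side="right")) - 1
    else:
        mean = n_walsh / 2.0
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k_crit = int(math.floor(mean - stats.norm.ppf(1.0 - alpha / 2.0) * sd)) - 1
    trim = max(0, min(k_crit, n_walsh // 2 - 1))
    lo = float(walsh[trim])
    hi = float(walsh[n_walsh - 1 - trim])
    return estimate, lo, hi


@dataclass(frozen=True)
class TheilFit:
    """Robust line fit: median-of-pairwise-slopes with Spearman correlation."""

    alpha: float
    alpha_ci: tuple[float, float]
    beta: float
    beta_ci: tuple[float, float]
    rho_s: float
    p_rho: float
    n: int


def theil_regression(xs, ys, conf: float = 0.95) -> TheilFit:
    """Theil line fit with rank-based CIs and tie-corrected Spearman ρ.

    Slope = median of all pairwise slopes (xᵢ ≠ xⱼ); intercept = median of
    (yᵢ − β·xᵢ); the slope CI is the classical rank-based interval and the
    intercept CI the signed-rank interval of the residual location.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys):
        raise ValueError("xs and ys must have equal length")
    if len(xs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(xs).any() or np.isnan(ys).any():
        raise ValueError("theil_regression requires data without missing values")
    if np.all(xs == xs[0]):
        raise ValueError("all abscissa values identical")
    beta, alpha_hat, beta_lo, beta_hi = stats.theilslopes(
        ys, xs, alpha=conf, method="joint"
    )
    residuals = ys - beta * xs
    _, alpha_lo, alpha_hi = hl_median_ci(residuals, conf=conf)
    if np.all(ys == ys[0]):
        rho, p_rho = 0.0, 1.0  # correlation with a constant carries no trend
    else:
        rho, p_rho = stats.spearmanr(xs, ys)
    return TheilFit(
        alpha=float(alpha_hat),
        alpha_ci=(float(alpha_lo), float(alpha_hi)),
        beta=float(beta),
        beta_ci=(float(beta_lo), float(beta_hi)),
        rho_s=float(rho),
        p_rho=float(p_rho),
        n=len(xs),
    )


def jarque_bera(ys) -> tuple[float, float]:
    """Jarque–Bera Gaussianity statistic JB = n/6·(S² + (K − 3)²/4).

    S and K are the population-moment sample skewness and kurtosis; the
    p-value comes from the asymptotic χ²₂ reference.
    """
    ys = np.asarray(ys, dtype=float)
    n = len(ys)
    if n < 4:
        raise ValueError("need at least 4 observations")
    centered = ys - ys.mean()
    m2 = float(np.mean(centered**2))
    if m2 == 0:
        raise ValueError("zero variance")
    skew = float(np.mean(centered**3)) / m2**1.5
    kurt = float(np.mean(centered**4)) / m2**2
    jb = n / 6.0 * (skew**2 + (kurt - 3.0) ** 2 / 4.0)
    return jb, float(stats.chi2.sf(jb, 2))


def smirnov_two_sample(a, b) -> tuple[float, float]:
    """Two-sided Smirnov comparison of two samples' empirical CDFs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    result = stats.ks_2samp(a, b, method="asymp")
    return float(result.statistic), float(result.pvalue)
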