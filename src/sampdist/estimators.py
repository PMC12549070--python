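"""Point estimators and tests applied inside the simulations.

Covers the classical and robust statistics the simulations repeatedly apply
to each simulated experiment:

* Pearson and Spearman correlation with two-sided p-values,
* the 20% trimmed mean and the matching winsorized variance,
* the one-sample Yuen trimmed-mean t test,
* the Harrell–Davis weighted-order-statistic quantile estimator,
* the exact null CDF of Pearson's r under bivariate normality (an analytic
  oracle: under rho = 0, r² follows a Beta(1/2, (n−2)/2) distribution).

Trimming convention: a trim proportion ``gamma`` removes ``g = floor(gamma*n)``
observations from each tail (the standard robust-statistics convention), so
``h = n - 2g`` observations remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "TestResult",
    "pearson",
    "spearman",
    "trimmed_mean",
    "winsorized_variance",
    "winsorize",
    "yuen_one_sample",
    "harrell_davis_quantile",
    "harrell_davis_weights",
    "pearson_null_within",
    "pearson_critical_r",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a test: point estimate, test statistic, df and two-sided p."""

    estimate: float
    statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def _check_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (x, y) observations")
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 pairs for a correlation test, got {n}")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    return x, y


def _corr_result(r: float, n: int) -> TestResult:
    df = n - 2
    if abs(r) >= 1.0:  # collinear: p is exactly 0
        return TestResult(estimate=float(np.sign(r)), statistic=math.inf * np.sign(r), df=df, p_value=0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(estimate=r, statistic=t, df=df, p_value=min(p, 1.0))


def pearson(pairs) -> TestResult:
    """Pearson product-moment correlation with a two-sided t-based p-value.

    p comes from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    x, y = _check_pairs(pairs)
    r = float(stats.pearsonr(x, y).statistic)
    return _corr_result(r, x.size)


def spearman(pairs) -> TestResult:
    """Spearman rank correlation: Pearson on mid-ranks, same t-based p-value."""
    x, y = _check_pairs(pairs)
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("correlation undefined: a rank vector is constant")
    r = float(stats.pearsonr(rx, ry).statistic)
    return _corr_result(r, x.size)


# ---------------------------------------------------------------------------
# trimmed means / Yuen
# ---------------------------------------------------------------------------


def _check_trim(values, trim: float, min_kept: int = 1) -> np.ndarray:
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim proportion must lie in [0, 0.5), got {trim}")
    arr = np.asarray(values, dtype=float).ravel()
    n = arr.size
    if n < 1:
        raise ValueError("empty sample")
    g = int(math.floor(trim * n))
    if n - 2 * g < min_kept:
        raise ValueError(
            f"sample too small: n={n} with trim={trim} keeps {n - 2 * g} < {min_kept} values"
        )
    return arr


def trimmed_mean(values, trim: float = 0.2) -> float:
    """Mean after discarding the lowest and highest ``floor(trim*n)`` values.

    ``trim=0`` is the ordinary mean, ``trim→0.5`` approaches the median.
    """
    arr = _check_trim(values, trim)
    return float(stats.trim_mean(arr, trim))


def winsorize(values, trim: float = 0.2) -> np.ndarray:
    """Replace each trimmed tail by its nearest retained order statistic (sorted)."""
    arr = np.sort(_check_trim(values, trim))
    g = int(math.floor(trim * arr.size))
    if g:
        arr[:g] = arr[g]
        arr[-g:] = arr[-g - 1]
    return arr


def winsorized_variance(values, trim: float = 0.2) -> float:
    """Sample variance (ddof=1) of the winsorized sample.

    The variance component of Yuen-type trimmed-mean tests; ``trim=0``
    reduces to the ordinary sample variance.
    """
    arr = _check_trim(values, trim, min_kept=1)
    if arr.size < 2:
        raise ValueError("winsorized variance needs n >= 2")
    return float(np.var(winsorize(arr, trim), ddof=1))


def yuen_one_sample(values, trim: float = 0.2, null_value: float = 0.0) -> TestResult:
    """One-sample Yuen test of a trimmed mean against ``null_value``.

    With n observations, g = floor(trim·n) trimmed per tail and h = n − 2g
    retained, the statistic is

        t = (trimmed_mean − null_value) / SE,
        SE = sqrt((n − 1) · s²_w / (h · (h − 1))),

    where s²_w is the winsorized variance, on h − 1 degrees of freedom with a
    two-sided Student-t p-value.  At trim = 0 this is exactly the classic
    one-sample t test.
    """
    arr = _check_trim(values, trim, min_kept=2)
    n = arr.size
    g = int(math.floor(trim * n))
    h = n - 2 * g
    tm = trimmed_mean(arr, trim)
    wv = winsorized_variance(arr, trim)
    se = math.sqrt((n - 1) * wv / (h * (h - 1)))
    df = h - 1
    if se == 0:
        stat = 0.0 if tm == null_value else math.copysign(math.inf, tm - null_value)
        p = 1.0 if tm == null_value else 0.0
    else:
        stat = (tm - null_value) / se
        p = 2.0 * stats.t.sf(abs(stat), df)
    return TestResult(estimate=tm, statistic=stat, df=df, p_value=min(p, 1.0))


# ---------------------------------------------------------------------------
# Harrell–Davis quantiles
# ---------------------------------------------------------------------------


def harrell_davis_weights(n: int, q: float) -> np.ndarray:
    """Incomplete-beta weights on the order statistics for the HD estimator.

    Weight i (1-based) is the Beta((n+1)q, (n+1)(1−q)) probability mass on
    ((i−1)/n, i/n]; the weights sum to 1.
    """
    if n < 1:
        raise ValueError("need at least one observation")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    a = (n + 1) * q
    b = (n + 1) * (1.0 - q)
    edges = np.arange(n + 1) / n
    cdf = special.betainc(a, b, edges)
    return np.diff(cdf)


def harrell_davis_quantile(values, q: float = 0.5) -> float:
    """Harrell–Davis estimate of the q-th quantile.

    A smooth weighted average of all order statistics; handles tied values
    better than single-order-statistic quantile estimators.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty sample")
    w = harrell_davis_weights(arr.size, q)
    return float(np.sort(arr) @ w)


# ---------------------------------------------------------------------------
# exact Pearson null distribution
# ---------------------------------------------------------------------------


def pearson_null_within(margin: float, n: int) -> float:
    """Exact P(|r| ≤ margin) for Pearson's r under rho = 0, bivariate normal.

    Under the null, r² ~ Beta(1/2, (n−2)/2), so the probability is the
    regularized incomplete beta function evaluated at margin².  Strictly
    increasing in both n and margin; the analytic backbone of the
    correlation precision curves.
    """
    if not 0.0 < margin <= 1.0:
        raise ValueError(f"margin must lie in (0, 1], got {margin}")
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    return float(special.betainc(0.5, (n - 2) / 2.0, margin**2))


def pearson_critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| reaching two-sided significance at level alpha for size n."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    df = n - 2
    t_crit = stats.t.isf(alpha / 2.0, df)
    return float(t_crit / math.sqrt(df + t_crit**2))
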