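"""Distribution diagnostics for simulated (or observed) fruit weights.

Provides the skewness z-test, one- and two-sample Kolmogorov-Smirnov
tests, maximum-likelihood fits of the normal and the 3-parameter
(shifted) lognormal families, Q-Q data, and histogram binning.

Caveat on goodness-of-fit p-values: when a family's parameters are
estimated from the very sample being tested, plain K-S p-values are
anticonservative (the Lilliefors effect).  They are reported as-is —
the standard practice this suite mirrors — and should be read as
descriptive, not as calibrated test levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats


class FitConvergenceError(RuntimeError):
    """Raised when a distribution fit fails to reach a usable optimum."""


@dataclass(frozen=True)
class SkewnessReport:
    """Adjusted Fisher-Pearson sample skewness G1 with its standard error.

    ``z_score = skewness / se_skewness``; |z| above ~2 indicates
    significant asymmetry at large n.
    """

    n: int
    skewness: float
    se_skewness: float
    z_score: float


@dataclass(frozen=True)
class LognormalFit:
    """3-parameter lognormal MLE: shape ``s``, location ``loc``, ``scale``.

    The density is that of loc + scale * exp(s * Normal(0,1)); as s -> 0
    it approaches a normal shape, so for mildly skewed data the raw
    parameters sit on a near-flat likelihood ridge and only the implied
    moments are stably identified.
    """

    s: float
    loc: float
    scale: float
    log_likelihood: float
    ks_stat: float
    ks_pvalue: float

    @property
    def mean(self) -> float:
        return float(stats.lognorm.mean(self.s, self.loc, self.scale))

    @property
    def sd(self) -> float:
        return float(stats.lognorm.std(self.s, self.loc, self.scale))

    def cdf(self, x):
        return stats.lognorm.cdf(x, self.s, self.loc, self.scale)


@dataclass(frozen=True)
class NormalFit:
    mean: float
    sd: float
    log_likelihood: float
    ks_stat: float
    ks_pvalue: float

    def cdf(self, x):
        return stats.norm.cdf(x, self.mean, self.sd)


def se_skewness(n: int) -> float:
    """Large-sample standard error of G1: sqrt(6n(n-1) / ((n-2)(n+1)(n+3)))."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    n = float(n)
    return float(np.sqrt(6.0 * n * (n - 1.0) / ((n - 2.0) * (n + 1.0) * (n + 3.0))))


def skewness_report(sample: Sequence[float]) -> SkewnessReport:
    """Adjusted Fisher-Pearson skewness G1, its SE, and the z-score G1/SE."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance; skewness undefined")
    g1 = float(stats.skew(x, bias=False))
    se = se_skewness(x.size)
    return SkewnessReport(n=int(x.size), skewness=g1, se_skewness=se, z_score=g1 / se)


def ks_one_sample(sample: Sequence[float], cdf: Callable) -> tuple[float, float]:
    """One-sample K-S test of ``sample`` against a fully specified CDF.

    Returns (D, p) with D = sup |empirical CDF - cdf| and p from the
    asymptotic Kolmogorov distribution.  Against a discrete
    (right-continuous step) CDF the test is conservative; prefer
    :func:`chisquare_counts` for discrete nulls.
    """
    res = stats.kstest(np.asarray(sample, dtype=float), cdf, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample K-S test; asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chisquare_counts(
    values: Sequence[int], pmf: np.ndarray, min_expected: float = 5.0
) -> tuple[float, float]:
    """Chi-square goodness of fit of integer draws against an exact pmf.

    Bins are the pmf's support values; adjacent low-expectation bins
    (expected count < ``min_expected``) are pooled from the right tail.
    Suited to discrete nulls where the K-S test is conservative.
    Returns (chi2, p) with dof = #bins - 1 (no parameters estimated).
    """
    values = np.asarray(values)
    n = values.size
    support = np.arange(len(pmf))
    observed = np.bincount(values, minlength=len(pmf)).astype(float)
    expected = pmf * n

    # pool from the right until every bin has enough expectation
    obs_bins, exp_bins = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_bins.append(acc_o)
            exp_bins.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and obs_bins:
        obs_bins[-1] += acc_o
        exp_bins[-1] += acc_e
    obs_arr = np.array(obs_bins)
    exp_arr = np.array(exp_bins)
    exp_arr *= obs_arr.sum() / exp_arr.sum()  # absorb truncated tail mass
    chi2, p = stats.chisquare(obs_arr, exp_arr)
    return float(chi2), float(p)


def _lognorm_profile_params(x: np.ndarray, loc: float) -> tuple[float, float]:
    # closed-form (s, scale) MLE of the shifted sample at fixed loc
    logx = np.log(x - loc)
    return float(logx.std()), float(np.exp(logx.mean()))


def _lognorm_loglik(x: np.ndarray, s: float, loc: float, scale: float) -> float:
    return float(stats.lognorm.logpdf(x, s, loc, scale).sum())


def fit_lognormal3(sample: Sequence[float]) -> LognormalFit:
    """Maximum-likelihood fit of the 3-parameter (shifted) lognormal.

    Strategy: at fixed ``loc`` the (s, scale) MLE is available in closed
    form from the log-moments of the shifted sample, so the fit profiles
    the likelihood over ``loc`` on a log-spaced grid of offsets below
    min(sample) (1e-5 to 1e2 of the sample range), refines the best
    bracket with bounded 1-D optimization, and finally accepts a joint
    ``scipy.stats.lognorm.fit`` polish only if it improves the
    likelihood while keeping loc < min(sample).  The grid's lower bound
    keeps the search away from the unbounded-likelihood spike at
    loc -> min(sample) that makes the global 3-parameter MLE ill-posed.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 observations, got {x.size}")
    xmin = float(x.min())
    xrange = float(np.ptp(x))
    if xrange == 0:
        raise ValueError("sample has zero range; lognormal fit undefined")

    offsets = xrange * np.logspace(-5.0, 2.0, 71)
    lls = np.empty(len(offsets))
    for j, off in enumerate(offsets):
        s_j, scale_j = _lognorm_profile_params(x, xmin - off)
        lls[j] = _lognorm_loglik(x, s_j, xmin - off, scale_j)
    i = int(np.argmax(lls))

    def neg_profile_ll(log10_off: float) -> float:
        loc = xmin - xrange * 10.0**log10_off
        s, scale = _lognorm_profile_params(x, loc)
        return -_lognorm_loglik(x, s, loc, scale)

    lo = np.log10(offsets[max(i - 1, 0)] / xrange)
    hi = np.log10(offsets[min(i + 1, len(offsets) - 1)] / xrange)
    res = optimize.minimize_scalar(neg_profile_ll, bounds=(lo, hi), method="bounded")
    loc = xmin - xrange * 10.0**float(res.x)
    s, scale = _lognorm_profile_params(x, loc)
    ll = _lognorm_loglik(x, s, loc, scale)

    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            s2, loc2, scale2 = stats.lognorm.fit(x, s, loc=loc, scale=scale)
        if loc2 < xmin and s2 > 0:
            ll2 = _lognorm_loglik(x, s2, loc2, scale2)
            if np.isfinite(ll2) and ll2 > ll:
                s, loc, scale, ll = float(s2), float(loc2), float(scale2), ll2
    except Exception:  # joint polish is best-effort; profile result stands
        pass

    if not (np.isfinite(ll) and s > 0 and scale > 0 and loc < xmin):
        raise FitConvergenceError(
            f"lognormal fit did not converge: s={s}, loc={loc}, scale={scale}, "
            f"loglik={ll}, optimizer={res}"
        )
    d, p = ks_one_sample(x, lambda v: stats.lognorm.cdf(v, s, loc, scale))
    return LognormalFit(s=s, loc=loc, scale=scale, log_likelihood=ll, ks_stat=d, ks_pvalue=p)


def fit_normal(sample: Sequence[float]) -> NormalFit:
    """Normal fit by sample mean and SD (ddof=1) with K-S goodness of fit."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 observations, got {x.size}")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("sample has zero variance; normal fit degenerate")
    ll = float(stats.norm.logpdf(x, m, sd).sum())
    d, p = ks_one_sample(x, lambda v: stats.norm.cdf(v, m, sd))
    return NormalFit(mean=m, sd=sd, log_likelihood=ll, ks_stat=d, ks_pvalue=p)


def qq_points(sample: Sequence[float]) -> np.ndarray:
    """Normal Q-Q data: (theoretical quantile, ordered sample value) pairs.

    Theoretical quantiles are taken at plotting positions (i - 0.5) / n
    and rescaled by the sample mean and SD, so points from a normal
    sample fall near the identity line.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    probs = (np.arange(1, n + 1) - 0.5) / n
    theo = x.mean() + x.std(ddof=1) * stats.norm.ppf(probs)
    return np.column_stack([theo, x])


def freedman_diaconis_histogram(sample: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts and bin edges using the Freedman-Diaconis rule."""
    x = np.asarray(sample, dtype=float)
    counts, edges = np.histogram(x, bins="fd")
    return counts, edges
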