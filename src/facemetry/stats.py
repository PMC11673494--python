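"""Agreement and inference layer.

Implements the statistics used to judge a paired scan/reconstruction
study: two-way absolute-agreement intraclass correlation (single and
average measures, with F-based confidence intervals), paired t tests
from raw pairs or printed summaries, t-based confidence intervals for a
mean, the Shapiro-Wilk normality gate, and a priori paired-design sample
size from Cohen's d via the noncentral t distribution.

All p values are two-sided.  No multiple-testing correction is applied
by default (a Bonferroni option exists in the measurement comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidArgumentError


# ---------------------------------------------------------------------------
# intraclass correlation, two-way random effects, absolute agreement
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    """Two-way absolute-agreement ICC.

    ``icc_single`` is ICC(A,1) — the reliability of one rating;
    ``icc_average`` is ICC(A,k) — the reliability of the k-rater mean.
    Variance components come from the two-way random-effects ANOVA.
    """

    icc_single: float
    icc_average: float
    ci_single: Tuple[float, float]
    ci_average: Tuple[float, float]
    var_subjects: float
    var_raters: float
    var_residual: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int

    def summary(self) -> str:
        return (
            f"ICC two-way absolute agreement (n={self.n} subjects, k={self.k} raters)\n"
            f"  single measures  ICC(A,1) = {self.icc_single:.4f} "
            f"(95% CI {self.ci_single[0]:.4f}-{self.ci_single[1]:.4f})\n"
            f"  average measures ICC(A,{self.k}) = {self.icc_average:.4f} "
            f"(95% CI {self.ci_average[0]:.4f}-{self.ci_average[1]:.4f})"
        )


def icc_two_way_absolute(ratings: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1) and ICC(A,k) from an n-subjects x k-raters matrix.

    Mean squares follow the two-way random-effects ANOVA; the absolute-
    agreement single-measures coefficient is
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` and the
    average-measures form drops the (k-1) MSE rater penalty.  Confidence
    intervals use the standard F-based construction with a Satterthwaite
    degrees-of-freedom approximation for the rater term.
    """
    X = np.asarray(ratings, float)
    if X.ndim != 2:
        raise InvalidArgumentError("ratings must be a 2-D matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise InvalidArgumentError("need at least 3 subjects and 2 raters")
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("ratings contain missing or non-finite cells")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    icc1 = (msr - mse) / denom_single if denom_single != 0 else np.nan
    denom_avg = msr + (msc - mse) / n
    icck = (msr - mse) / denom_avg if denom_avg != 0 else np.nan

    alpha = 1.0 - confidence
    # F-based CI for ICC(A,1) (Satterthwaite df for the rater term)
    if mse > 0 and np.isfinite(icc1):
        a = k * icc1 / (n * (1 - icc1)) if icc1 != 1 else np.inf
        b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1)) if icc1 != 1 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lower1 = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper1 = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
        else:
            lower1 = upper1 = 1.0
    else:
        lower1, upper1 = np.nan, np.nan
        if mse == 0:
            lower1 = upper1 = icc1

    def spearman_brown(r: float) -> float:
        if not np.isfinite(r):
            return r
        return k * r / (1 + (k - 1) * r)

    return ICCResult(
        icc_single=float(icc1),
        icc_average=float(icck),
        ci_single=(float(lower1), float(upper1)),
        ci_average=(float(spearman_brown(lower1)), float(spearman_brown(upper1))),
        var_subjects=float((msr - mse) / k),
        var_raters=float((msc - mse) / n),
        var_residual=float(mse),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n=n,
        k=k,
    )


# ---------------------------------------------------------------------------
# paired t tests
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    mean_diff: float
    sd_diff: float
    n: int
    t: float
    df: int
    p: float
    degenerate: Optional[str] = None

    def summary(self) -> str:
        return (
            f"paired t: mean diff {self.mean_diff:.4g} ± {self.sd_diff:.4g}, "
            f"n={self.n}, t({self.df}) = {self.t:.3f}, p = {self.p:.4g}"
        )


def paired_t_from_pairs(x: np.ndarray, y: np.ndarray) -> PairedTestResult:
    """Two-sided paired t test on d = x − y."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise InvalidArgumentError("paired vectors must have equal length")
    n = x.size
    if n < 2:
        raise InvalidArgumentError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        if mean == 0:
            return PairedTestResult(mean, sd, n, 0.0, df, 1.0, degenerate="all-zero differences")
        t = np.inf if mean > 0 else -np.inf
        return PairedTestResult(mean, sd, n, t, df, 0.0, degenerate="zero variance")
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTestResult(mean, sd, n, float(t), df, float(p))


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> PairedTestResult:
    """Paired t test recomputed from a printed mean ± SD of differences."""
    if n < 2:
        raise InvalidArgumentError("need n >= 2")
    if sd_diff <= 0:
        raise InvalidArgumentError("sd_diff must be > 0")
    t = mean_diff / (sd_diff / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTestResult(float(mean_diff), float(sd_diff), int(n), float(t), df, float(p))


def mean_ci(mean: float, sd: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """t-based confidence interval for a mean from summary statistics."""
    if n < 2:
        raise InvalidArgumentError("need n >= 2")
    if not (0 < level < 1):
        raise InvalidArgumentError("confidence level must be in (0, 1)")
    if sd < 0:
        raise InvalidArgumentError("sd must be >= 0")
    half = sps.t.ppf((1 + level) / 2, n - 1) * sd / np.sqrt(n)
    return (float(mean - half), float(mean + half))


def shapiro_wilk(x: np.ndarray) -> Tuple[float, float]:
    """Shapiro-Wilk W statistic and p value (normality gate)."""
    x = np.asarray(x, float).ravel()
    if not (3 <= x.size <= 5000):
        raise InvalidArgumentError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateInputError("sample is constant")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# paired-design sample size from Cohen's d
# ---------------------------------------------------------------------------

@dataclass
class SampleSizeResult:
    n: int
    achieved_power: float
    power_at_n_minus_1: float

    def summary(self) -> str:
        return (
            f"minimum n = {self.n} "
            f"(power {self.achieved_power:.4f}; at n-1: {self.power_at_n_minus_1:.4f})"
        )


def paired_t_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Two-sided paired-t power at sample size n for effect size d
    (Cohen's d on the paired differences), from the noncentral t
    distribution with df = n − 1 and noncentrality d·sqrt(n)."""
    if n < 2:
        return 0.0
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    nc = d * np.sqrt(n)
    return float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def paired_sample_size(
    d: float, power: float = 0.95, alpha: float = 0.05, n_max: int = 1_000_000
) -> SampleSizeResult:
    """Smallest n ≥ 2 whose two-sided paired-t power reaches the target.

    Exact integer scan upward from n = 2 (cheap and unambiguous).
    """
    if d <= 0:
        raise InvalidArgumentError("effect size d must be > 0")
    if not (0 < power < 1) or not (0 < alpha < 1):
        raise InvalidArgumentError("power and alpha must be in (0, 1)")
    prev = 0.0
    for n in range(2, n_max + 1):
        p = paired_t_power(n, d, alpha)
        if p >= power:
            return SampleSizeResult(n=n, achieved_power=p, power_at_n_minus_1=prev)
        prev = p
    raise InvalidArgumentError(f"target power not attained by n = {n_max}")
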