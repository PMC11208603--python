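"""Resampling and regression utilities.

Estimation-statistics style bootstrap of the mean with a BCa 95% interval,
a two-sided permutation test for a difference of means with the add-one
p-value convention (minimum attainable p = 1/(n_perm+1)), the classical
paired t-test, and simple linear regression with a 95% confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class BootstrapResult:
    estimate: float
    distribution: np.ndarray  # resampled means
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_mean_ci(values, n_boot: int = 5000,
                      seed: int = 0) -> BootstrapResult:
    """Bootstrap the sample mean with a bias-corrected-and-accelerated CI.

    Resamples with replacement; deterministic given the seed. A constant
    sample yields a zero-width interval at the constant.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    if np.ptp(x) == 0:  # degenerate: BCa undefined, interval is a point
        dist = np.full(n_boot, x[0])
        return BootstrapResult(float(x[0]), dist, float(x[0]), float(x[0]),
                               n_boot, seed)
    res = sps.bootstrap((x,), np.mean, n_resamples=n_boot, method="BCa",
                        confidence_level=0.95, rng=rng)
    return BootstrapResult(
        estimate=float(x.mean()),
        distribution=np.asarray(res.bootstrap_distribution),
        ci_low=float(res.confidence_interval.low),
        ci_high=float(res.confidence_interval.high),
        n_boot=n_boot, seed=seed)


def permutation_test(sample_a, sample_b, n_perm: int = 5000,
                     seed: int = 0, alternative: str = "two-sided") -> float:
    """Permutation p-value for a difference of group means.

    p = (1 + #{permuted |Δ| ≥ observed |Δ|}) / (1 + n_perm), so p is never
    zero and respects the add-one lower bound.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    rng = np.random.default_rng(seed)
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:a.size].mean() - perm[a.size:].mean()
        if alternative == "two-sided":
            count += abs(diff) >= abs(obs)
        elif alternative == "greater":
            count += diff >= obs
        else:
            count += diff <= obs
    return (1 + count) / (1 + n_perm)


def paired_t(values_a, values_b) -> tuple[float, int, float]:
    """Classical paired t-test on the per-pair differences.

    Returns (t, df, p) with df = n − 1. Zero-variance differences are an
    error (the statistic is undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, a.size - 1, 1.0
        raise ValueError("zero-variance differences: t undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


@dataclass
class LinregResult:
    slope: float
    intercept: float
    r2: float
    p: float
    slope_se: float
    slope_ci: tuple[float, float]
    n: int
    x_mean: float
    sxx: float
    resid_var: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def ci_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """95% confidence band for the mean response at ``x``."""
        x = np.asarray(x, dtype=float)
        tcrit = sps.t.ppf(0.975, self.n - 2)
        se = np.sqrt(self.resid_var *
                     (1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx))
        yhat = self.predict(x)
        return yhat - tcrit * se, yhat + tcrit * se


def simple_linreg(x, y) -> LinregResult:
    """Ordinary least squares of y on x with a standard confidence band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    n = x.size
    resid = y - (res.intercept + res.slope * x)
    resid_var = float(np.sum(resid ** 2) / (n - 2))
    sxx = float(np.sum((x - x.mean()) ** 2))
    tcrit = sps.t.ppf(0.975, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return LinregResult(slope=float(res.slope), intercept=float(res.intercept),
                        r2=float(res.rvalue ** 2), p=float(res.pvalue),
                        slope_se=float(res.stderr),
                        slope_ci=(float(ci[0]), float(ci[1])), n=n,
                        x_mean=float(x.mean()), sxx=sxx, resid_var=resid_var)
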