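"""Statistics layer: t-tests, BH-FDR, Hedge's g, lowess, detectable effect size.

All tests are two-sided.  FDR families are defined by the calling analysis
(per figure / per topography) and passed in explicitly as one p-value vector;
nothing here applies a hidden global correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    """One t-test: statistic, two-sided p, FDR-adjusted p (NaN until a family
    correction is applied by the caller), Hedge's g, sample size and df."""

    t: float
    p: float
    p_fdr: float
    g: float
    n: int
    df: int


def hedges_g(values: np.ndarray, popmean: float = 0.0) -> float:
    """Bias-corrected standardized mean difference g = d * J.

    ``J = 1 - 3 / (4 df - 1)`` with df = n - 1 (one-sample / paired samples:
    pass the within-pair differences).
    """
    values = np.asarray(values, float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two values")
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0 if values.mean() == popmean else np.nan
    d = (values.mean() - popmean) / sd
    df = n - 1
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return d * j


def one_sample_t(values: np.ndarray, popmean: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test against ``popmean``.

    Zero-variance input yields NaN t/p (undefined), never a spurious rejection.
    """
    values = np.asarray(values, float)
    values = values[~np.isnan(values)]
    n = values.size
    if n < 2:
        raise ValueError("need at least two non-missing values")
    if values.std(ddof=1) == 0:
        return TestResult(np.nan, np.nan, np.nan, hedges_g(values, popmean), n, n - 1)
    res = sps.ttest_1samp(values, popmean)
    return TestResult(float(res.statistic), float(res.pvalue), np.nan,
                      hedges_g(values, popmean), n, n - 1)


def paired_t(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided paired t-test, as a one-sample test on the differences."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal shape")
    return one_sample_t(a - b, 0.0)


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up across one explicit family of tests.

    Parameters
    ----------
    pvalues : array-like
        Raw two-sided p-values; NaNs (undefined tests) are never significant
        and receive adjusted p = NaN.
    q : float
        Target false discovery rate.

    Returns
    -------
    reject : boolean ndarray
    p_adjusted : ndarray, monotone non-decreasing with the raw rank.
    """
    p = np.asarray(pvalues, float).ravel()
    reject = np.zeros(p.size, bool)
    p_adj = np.full(p.size, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        reject[ok] = rej
        p_adj[ok] = adj
    return reject, p_adj


def lowess(y: np.ndarray, x: np.ndarray | None = None, span: float | int = 5,
           x_span: float | None = None) -> np.ndarray:
    """Locally weighted (tricube) linear smoothing of a series.

    ``span`` is the window expressed as a number of points, or give ``x_span``
    in x-units (e.g. seconds).  Exact on globally linear input in the
    interior; constant input passes through unchanged.  NaN gaps are smoothed
    over (dropped from the fit, evaluated everywhere).
    """
    y = np.asarray(y, float)
    if x is None:
        x = np.arange(y.size, dtype=float)
    x = np.asarray(x, float)
    if x_span is not None:
        step = np.median(np.diff(x))
        span = max(3.0, x_span / step)
    if span < 3:
        raise ValueError("span must cover at least 3 samples")
    ok = ~np.isnan(y)
    if ok.sum() < 3:
        return y.copy()
    frac = min(1.0, float(span) / ok.sum())
    out = _sm_lowess(y[ok], x[ok], frac=frac, it=0, xvals=x)
    return np.asarray(out, float)


def _power_two_sided(d: float, n: int, alpha: float) -> float:
    """Power of a two-sided one-sample t at effect d, via the noncentral t."""
    df = n - 1
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * np.sqrt(n)
    val = sps.nct.sf(tc, df, nc) + sps.nct.cdf(-tc, df, nc)
    if not np.isfinite(val):  # extreme noncentrality overflows the quadrature
        return 1.0 if nc > tc else 0.0
    return float(val)


def detectable_effect_size(alpha: float = 0.05, power: float = 0.8,
                           n: int = 18) -> dict[str, float]:
    """Smallest standardized effect a two-sided one-sample/paired t-test detects.

    Solves ``power(d) = power`` for the noncentrality ``d * sqrt(n)`` by root
    finding on the noncentral t distribution (post-hoc sensitivity analysis).

    Returns
    -------
    dict with keys ``d`` (Cohen) and ``g`` (small-sample corrected,
    ``g = d * (1 - 3/(4 df - 1))``).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2")
    d = optimize.brentq(lambda d_: _power_two_sided(d_, n, alpha) - power, 1e-8, 20.0,
                        xtol=1e-10)
    df = n - 1
    return {"d": float(d), "g": float(d * (1.0 - 3.0 / (4.0 * df - 1.0)))}
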