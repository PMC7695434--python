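"""Statistical primitives for clock comparison.

* age acceleration — estimated methylation age minus chronological age;
* test error — median absolute difference (years) between methylation and
  chronological age;
* OLS of methylation age on chronological age with residual standard error,
  which is invariant to adding any affine function of chronological age to
  the estimates;
* Hotelling-Williams t test for two dependent correlations sharing a
  variable (here: chronological age against two clocks on the same
  samples), with n - 3 degrees of freedom;
* Welch two-sample two-sided t test (unequal variances) on accelerations;
* two-sided variance-ratio F test on regression residuals;
* Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "age_acceleration",
    "test_error",
    "fit_age_regression",
    "RegressionFit",
    "williams_test",
    "welch_t_test",
    "residual_se_test",
    "bh_adjust",
]


def age_acceleration(meth_age_years, chron_age_years) -> np.ndarray:
    """Elementwise methylation age minus chronological age; NaN propagates."""
    meth = np.asarray(meth_age_years, dtype=float)
    chron = np.asarray(chron_age_years, dtype=float)
    if meth.shape != chron.shape:
        raise ValueError("paired vectors must have equal length")
    return meth - chron


def test_error(meth_age_years, chron_age_years) -> float:
    """Median absolute difference in years between the two age vectors.

    The median of an even-length vector is the mean of the two central
    order statistics.  NaN pairs are excluded.
    """
    diff = age_acceleration(meth_age_years, chron_age_years)
    diff = diff[np.isfinite(diff)]
    if diff.size == 0:
        raise ValueError("no complete pairs")
    return float(np.median(np.abs(diff)))


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    residual_se: float
    residuals: np.ndarray
    n: int


def fit_age_regression(chron, meth) -> RegressionFit:
    """OLS of methylation age on chronological age.

    ``residual_se = sqrt(RSS / (n - 2))``.  The residuals are unchanged by
    adding any affine function of chronological age to the estimates, which
    makes them a deviation measure unaffected by tissue-specific offset or
    slope miscalibration.
    """
    chron = np.asarray(chron, dtype=float)
    meth = np.asarray(meth, dtype=float)
    ok = np.isfinite(chron) & np.isfinite(meth)
    chron, meth = chron[ok], meth[ok]
    n = chron.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(chron) == 0:
        raise ValueError("chronological age is constant")
    res = sps.linregress(chron, meth)
    fitted = res.intercept + res.slope * chron
    residuals = meth - fitted
    rss = float(np.sum(residuals**2))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_se=float(np.sqrt(rss / (n - 2))),
        residuals=residuals,
        n=n,
    )


def williams_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Hotelling-Williams t test for two dependent overlapping correlations.

    Tests H0: rho_jk = rho_jh where variable j is shared (n samples), using
    Williams's t with n - 3 degrees of freedom:

        t = (r_jk - r_jh) * sqrt( (n-1)(1+r_kh) /
              ( 2 |R| (n-1)/(n-3) + rbar^2 (1-r_kh)^3 ) )

    with rbar = (r_jk + r_jh)/2 and |R| the determinant of the 3x3
    correlation matrix.  Returns (t, two-sided p).
    """
    if n < 4:
        raise ValueError("Williams test needs n >= 4")
    for r in (r_jk, r_jh, r_kh):
        if not np.isfinite(r) or abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    det = 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
    rbar = 0.5 * (r_jk + r_jh)
    denom = 2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_kh) ** 3
    t = (r_jk - r_jh) * np.sqrt((n - 1) * (1 + r_kh) / denom)
    p = 2 * sps.t.sf(abs(t), df=n - 3)
    return float(t), float(min(p, 1.0))


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sample two-sided t test assuming unequal variances.

    Welch statistic with Welch-Satterthwaite degrees of freedom; NaNs are
    dropped.  Returns (t, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def residual_se_test(residuals_a, residuals_b) -> tuple[float, float]:
    """Two-sided variance-ratio F test on regression residual variances.

    ``F = (RSS_a/(n_a-2)) / (RSS_b/(n_b-2))`` with (n_a - 2, n_b - 2)
    degrees of freedom (residuals come from a two-parameter age
    regression); p is the two-sided tail.  Swapping inputs inverts F and
    leaves p unchanged.
    """
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each residual vector needs at least 3 values")
    dfa, dfb = a.size - 2, b.size - 2
    va = float(np.sum(a**2)) / dfa
    vb = float(np.sum(b**2)) / dfb
    if vb == 0 and va == 0:
        return 1.0, 1.0
    if vb == 0 or va == 0:
        return (np.inf if vb == 0 else 0.0), 0.0
    F = va / vb
    cdf = sps.f.cdf(F, dfa, dfb)
    p = 2 * min(cdf, 1 - cdf)
    return float(F), float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj
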