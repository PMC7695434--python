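"""Cohort-level clock evaluation and comparison.

Given age estimates for several clocks on the same samples this module
computes, per clock: Pearson r against chronological age, test error
(median absolute deviation in years), acceleration mean and sd, and the
chronological-to-methylation-age regression with its residual standard
error.  Clocks are then compared pairwise:

* correlation contrasts via the Hotelling-Williams test (the shared
  variable is chronological age), BH-corrected over the family of pairs;
* group contrasts (diagnosis / subtype / condition labels from the sample
  sheet) via Welch t tests on acceleration, BH-corrected per clock;
* residual-spread contrasts via a two-sided variance-ratio F test.

Score-only clocks (epiTOC) take part in correlation contrasts but are
excluded from acceleration and test-error summaries, since their score is
not an age in years.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .stats import (
    bh_adjust,
    fit_age_regression,
    residual_se_test,
    test_error,
    welch_t_test,
    williams_test,
)
from .types import AgeEstimates

__all__ = ["evaluate_clocks", "adjust_linear", "clock_metrics"]


def _clock_series(estimates: AgeEstimates, clock: str) -> pd.DataFrame:
    tab = estimates.for_clock(clock).set_index("sample_id")
    score = tab["score"].astype(float)
    y = score.where(score.notna(), tab["methylation_age_years"].astype(float))
    return pd.DataFrame(
        {
            "y": y.astype(float),
            "chron": tab["chronological_age_years"].astype(float),
            "accel": tab["acceleration_years"].astype(float),
        }
    )


def clock_metrics(estimates: AgeEstimates, score_only_clocks: set[str] | None = None) -> pd.DataFrame:
    """Per-clock evaluation table (one row per clock)."""
    score_only_clocks = score_only_clocks or _infer_score_only(estimates)
    rows = []
    for clock in estimates.clocks:
        d = _clock_series(estimates, clock)
        ok = d["y"].notna() & d["chron"].notna()
        n = int(ok.sum())
        row = {
            "clock": clock,
            "n": n,
            "pearson_r": np.nan,
            "test_error_years": np.nan,
            "acceleration_mean": np.nan,
            "acceleration_sd": np.nan,
            "slope": np.nan,
            "intercept": np.nan,
            "residual_se": np.nan,
        }
        if n >= 3 and d.loc[ok, "chron"].nunique() > 1 and d.loc[ok, "y"].nunique() > 1:
            row["pearson_r"] = float(
                np.corrcoef(d.loc[ok, "chron"], d.loc[ok, "y"])[0, 1]
            )
            fit = fit_age_regression(d.loc[ok, "chron"], d.loc[ok, "y"])
            row.update(
                slope=fit.slope, intercept=fit.intercept, residual_se=fit.residual_se
            )
        if clock not in score_only_clocks and n >= 1:
            row["test_error_years"] = test_error(d.loc[ok, "y"], d.loc[ok, "chron"])
            accel = d.loc[ok, "accel"].to_numpy(dtype=float)
            row["acceleration_mean"] = float(np.mean(accel))
            row["acceleration_sd"] = float(np.std(accel, ddof=1)) if n > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _infer_score_only(estimates: AgeEstimates) -> set[str]:
    t = estimates.table
    return {
        c
        for c in estimates.clocks
        if t.loc[t["clock"] == c, "score"].notna().any()
    }


def evaluate_clocks(
    estimates: AgeEstimates,
    sheet=None,
    group_column: str = "group",
    family: str = "cohort",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate and compare clocks on one cohort.

    Returns ``(metrics, contrasts)``.  ``metrics`` has one row per clock
    (see :func:`clock_metrics`).  ``contrasts`` holds Williams correlation
    contrasts for all clock pairs, residual-spread F contrasts, and Welch
    group contrasts on acceleration for every pair of group labels, each
    BH-adjusted within its labelled family.

    ``sheet`` (a :class:`~pediclocks.types.SampleSheet`) supplies the group
    labels; chronological ages are taken from the estimates themselves.
    """
    if len(estimates.table) == 0:
        raise ValueError("no estimates to evaluate")
    score_only = _infer_score_only(estimates)
    metrics = clock_metrics(estimates, score_only)

    contrasts: list[dict] = []
    clocks = estimates.clocks
    per_clock = {c: _clock_series(estimates, c) for c in clocks}

    # Williams contrasts on correlation with chronological age, all pairs
    will_rows = []
    for ca, cb in itertools.combinations(clocks, 2):
        da, db = per_clock[ca], per_clock[cb]
        common = da.index[da["y"].notna() & da["chron"].notna()]
        common = [s for s in common if s in db.index and np.isfinite(db.loc[s, "y"])]
        n = len(common)
        if n < 4:
            continue
        chron = da.loc[common, "chron"].to_numpy(dtype=float)
        ya = da.loc[common, "y"].to_numpy(dtype=float)
        yb = db.loc[common, "y"].to_numpy(dtype=float)
        if min(np.std(chron), np.std(ya), np.std(yb)) == 0:
            continue
        r_jk = float(np.corrcoef(chron, ya)[0, 1])
        r_jh = float(np.corrcoef(chron, yb)[0, 1])
        r_kh = float(np.corrcoef(ya, yb)[0, 1])
        if max(abs(r_jk), abs(r_jh), abs(r_kh)) >= 1:
            # degenerate (identical estimates): no difference to test
            will_rows.append((f"{ca} vs {cb}", 0.0, 1.0, n))
            continue
        t, p = williams_test(r_jk, r_jh, r_kh, n)
        will_rows.append((f"{ca} vs {cb}", t, p, n))
    if will_rows:
        padj = bh_adjust([r[2] for r in will_rows])
        for (label, t, p, n), ap in zip(will_rows, padj):
            contrasts.append(
                dict(
                    contrast=label,
                    kind="williams",
                    family=f"{family}/correlation",
                    statistic=t,
                    p_value=p,
                    adj_p_value=float(ap),
                    n=n,
                )
            )

    # residual-spread contrasts (F test on regression residuals), all pairs
    resid = {}
    for c in clocks:
        d = per_clock[c]
        ok = d["y"].notna() & d["chron"].notna()
        if ok.sum() >= 3 and d.loc[ok, "chron"].nunique() > 1:
            resid[c] = fit_age_regression(d.loc[ok, "chron"], d.loc[ok, "y"]).residuals
    f_rows = []
    for ca, cb in itertools.combinations([c for c in clocks if c in resid], 2):
        F, p = residual_se_test(resid[ca], resid[cb])
        f_rows.append((f"{ca} vs {cb}", F, p, len(resid[ca])))
    if f_rows:
        padj = bh_adjust([r[2] for r in f_rows])
        for (label, F, p, n), ap in zip(f_rows, padj):
            contrasts.append(
                dict(
                    contrast=label,
                    kind="residual_variance_F",
                    family=f"{family}/residual",
                    statistic=F,
                    p_value=p,
                    adj_p_value=float(ap),
                    n=n,
                )
            )

    # Welch group contrasts on acceleration, per clock family
    groups = None
    if sheet is not None and group_column in sheet.table.columns:
        groups = sheet.table[group_column].dropna()
    if groups is not None and groups.nunique() >= 2:
        for clock in clocks:
            if clock in score_only:
                continue
            d = per_clock[clock]
            rows = []
            labels = sorted(groups.unique())
            for ga, gb in itertools.combinations(labels, 2):
                sa = [s for s in groups.index[groups == ga] if s in d.index]
                sb = [s for s in groups.index[groups == gb] if s in d.index]
                aa = d.loc[sa, "accel"].dropna().to_numpy()
                ab = d.loc[sb, "accel"].dropna().to_numpy()
                if aa.size < 2 or ab.size < 2:
                    continue
                t, p = welch_t_test(aa, ab)
                rows.append(
                    (
                        f"{clock}: {ga} vs {gb}",
                        t,
                        p,
                        aa.size + ab.size,
                        float(np.mean(aa)),
                        float(np.mean(ab)),
                    )
                )
            if rows:
                padj = bh_adjust([r[2] for r in rows])
                for (label, t, p, n, ma, mb), ap in zip(rows, padj):
                    contrasts.append(
                        dict(
                            contrast=label,
                            kind="welch_t",
                            family=f"{family}/groups/{clock}",
                            statistic=t,
                            p_value=p,
                            adj_p_value=float(ap),
                            n=n,
                            mean_a=ma,
                            mean_b=mb,
                        )
                    )

    contrast_df = pd.DataFrame(
        contrasts,
        columns=[
            "contrast",
            "kind",
            "family",
            "statistic",
            "p_value",
            "adj_p_value",
            "n",
            "mean_a",
            "mean_b",
        ],
    )
    return metrics, contrast_df


def adjust_linear(estimates: AgeEstimates, reference: AgeEstimates | None = None) -> AgeEstimates:
    """Recalibrate each clock by the inverse of its fitted age regression.

    Fits methylation age on chronological age in the reference cohort
    (default: the estimates themselves) and applies the inverse affine map,
    so that the recalibrated estimates have slope 1 and intercept 0 against
    chronological age on that cohort.  Pearson r is unchanged.  Score-only
    clocks pass through untouched.  Off by default in the pipeline: headline
    analyses are unadjusted.
    """
    reference = reference or estimates
    out = estimates.table.copy()
    for clock in estimates.clocks:
        ref = reference.for_clock(clock)
        ok = ref["methylation_age_years"].notna() & ref["chronological_age_years"].notna()
        if ok.sum() < 3:
            continue
        fit = fit_age_regression(
            ref.loc[ok, "chronological_age_years"], ref.loc[ok, "methylation_age_years"]
        )
        if fit.slope == 0:
            continue
        mask = out["clock"] == clock
        adj = (out.loc[mask, "methylation_age_years"] - fit.intercept) / fit.slope
        out.loc[mask, "methylation_age_years"] = adj
        out.loc[mask, "native_value"] = adj
        out.loc[mask, "acceleration_years"] = (
            adj - out.loc[mask, "chronological_age_years"]
        )
    return AgeEstimates(out)
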