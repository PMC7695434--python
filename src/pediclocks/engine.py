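"""Clock evaluation engine: linear predictor, output transform, epiTOC score.

A coefficient clock predicts ``x_s = intercept + sum_j w_j * beta_{j,s}``
over its CpG set, maps ``x_s`` through the clock's inverse transform to the
native age unit, and converts to years.  Score-only clocks report the mean
beta over a fixed probe set (a mitotic-like score in [0, 1], not an age).

Missing clock probes are handled by policy:

* ``strict`` — error if any clock probe is absent or per-sample coverage
  falls below ``min_coverage``;
* ``drop`` — omit unavailable probes from the sum (no renormalisation);
* ``impute_mean`` (default) — fill missing betas with the cohort mean of the
  probe; probes absent from the matrix entirely are dropped with a warning.

Clocks are empirically robust to small sets of filtered-out probes, which is
why mean imputation is the default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import AgeEstimates, BetaMatrix, ClockModel, SampleSheet

logger = logging.getLogger(__name__)

__all__ = ["linear_predictor", "predict_age", "epitoc_score", "MissingProbes"]

POLICIES = ("strict", "drop", "impute_mean")


class MissingProbes(ValueError):
    """Raised under the strict policy when clock probes are unavailable."""


def _clock_betas(
    beta: BetaMatrix,
    clock: ClockModel,
    missing_policy: str,
    min_coverage: float,
) -> tuple[pd.DataFrame, pd.Series]:
    """Betas restricted to clock probes, with the missing policy applied.

    Returns the (possibly imputed) probe x sample frame plus per-sample
    probe coverage (fraction of the clock's probes with an observed value).
    """
    if missing_policy not in POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    wanted = clock.probe_ids
    if not wanted:
        # degenerate intercept-only clock
        empty = beta.values.iloc[0:0]
        return empty, pd.Series(1.0, index=beta.sample_ids, name="probe_coverage")
    present = [p for p in wanted if p in beta.values.index]
    absent = sorted(set(wanted) - set(present))
    if not present:
        raise MissingProbes(
            f"no probes of clock {clock.name!r} found in the beta matrix"
        )
    sub = beta.values.loc[present]
    observed = sub.notna()
    coverage = observed.sum(axis=0) / float(len(wanted))
    coverage.name = "probe_coverage"

    if missing_policy == "strict":
        if absent:
            raise MissingProbes(
                f"clock {clock.name!r}: probes absent from matrix: {absent[:10]}"
            )
        low = coverage[coverage < min_coverage]
        if len(low):
            raise MissingProbes(
                f"clock {clock.name!r}: probe coverage below {min_coverage:g} "
                f"for samples {list(low.index[:10])}"
            )
    elif missing_policy == "impute_mean":
        if absent:
            logger.warning(
                "clock %s: %d probe(s) absent from matrix, dropped", clock.name, len(absent)
            )
        means = sub.mean(axis=1, skipna=True)
        fully_missing = means.index[means.isna()]
        if len(fully_missing):
            sub = sub.drop(index=fully_missing)
            logger.warning(
                "clock %s: %d probe(s) with no observed value, dropped",
                clock.name,
                len(fully_missing),
            )
            means = means.drop(index=fully_missing)
        sub = sub.apply(lambda col: col.fillna(means), axis=0)
    else:  # drop
        if absent:
            logger.warning(
                "clock %s: %d probe(s) absent from matrix, omitted", clock.name, len(absent)
            )
    return sub, coverage


def linear_predictor(
    beta: BetaMatrix,
    clock: ClockModel,
    missing_policy: str = "impute_mean",
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Per-sample linear predictor of a coefficient clock.

    Returns a DataFrame indexed by sample id with columns ``x`` (the
    predictor value) and ``probe_coverage``.
    """
    if clock.score_only:
        raise ValueError(f"clock {clock.name!r} is score-only; use epitoc_score")
    sub, coverage = _clock_betas(beta, clock, missing_policy, min_coverage)
    if sub.shape[0] == 0:
        x = pd.Series(float(clock.intercept), index=sub.columns if sub.shape[1] else beta.sample_ids)
    else:
        weights = pd.Series(clock.coefficients).reindex(sub.index)
        # NaN betas contribute nothing to the sum
        x = clock.intercept + sub.mul(weights, axis=0).sum(axis=0, skipna=True)
    return pd.DataFrame({"x": x, "probe_coverage": coverage.reindex(x.index)})


def epitoc_score(
    beta: BetaMatrix,
    probe_set,
    missing_policy: str = "drop",
) -> pd.Series:
    """Mean beta over a fixed probe set per sample (score in [0, 1])."""
    probes = [p for p in probe_set if p in beta.values.index]
    if not probes:
        raise MissingProbes("no score probes found in the beta matrix")
    score = beta.values.loc[probes].mean(axis=0, skipna=True)
    score.name = "score"
    return score


def predict_age(
    beta: BetaMatrix,
    clock: ClockModel,
    sheet: SampleSheet | None = None,
    missing_policy: str = "impute_mean",
    min_coverage: float = 0.8,
) -> AgeEstimates:
    """Predict methylation age (or score) for every sample of ``beta``.

    If ``sheet`` is given, predictions are restricted to samples present in
    both inputs and acceleration (methylation age minus chronological age,
    in years) is computed where the chronological age is known.  Negative
    methylation ages are legitimate outputs and are not clamped.
    """
    if sheet is not None:
        common = [s for s in beta.sample_ids if s in set(sheet.sample_ids)]
        if not common:
            raise ValueError("no overlapping samples between beta matrix and sheet")
        beta = BetaMatrix(beta.values[common])
        chron = sheet.ages.reindex(common)
    else:
        common = beta.sample_ids
        chron = pd.Series(np.nan, index=common)

    if clock.score_only:
        score = epitoc_score(beta, clock.probe_set)
        sub, coverage = _clock_betas(beta, clock, "drop", min_coverage)
        df = pd.DataFrame(
            {
                "sample_id": common,
                "clock": clock.name,
                "native_value": score.reindex(common).to_numpy(),
                "methylation_age_years": np.nan,
                "chronological_age_years": chron.to_numpy(),
                "acceleration_years": np.nan,
                "score": score.reindex(common).to_numpy(),
                "probe_coverage": coverage.reindex(common).to_numpy(),
            }
        )
        return AgeEstimates(df)

    pred = linear_predictor(beta, clock, missing_policy, min_coverage)
    native = clock.transform.inverse(pred["x"].to_numpy())
    years = native / 12.0 if clock.native_unit == "months" else native
    chron_arr = chron.to_numpy()
    accel = np.where(np.isfinite(chron_arr), years - chron_arr, np.nan)
    df = pd.DataFrame(
        {
            "sample_id": common,
            "clock": clock.name,
            "native_value": native,
            "methylation_age_years": years,
            "chronological_age_years": chron_arr,
            "acceleration_years": accel,
            "score": np.nan,
            "probe_coverage": pred["probe_coverage"].reindex(common).to_numpy(),
        }
    )
    return AgeEstimates(df)
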