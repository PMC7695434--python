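"""Core domain types for methylation-age analysis.

The containers here are thin, validated wrappers around pandas objects:

* :class:`BetaMatrix` — CpG probes x samples matrix of methylation beta
  values in [0, 1] (``NaN`` marks missing).
* :class:`SampleSheet` — per-sample chronological age (years), tissue and
  group labels.
* :class:`ClockModel` — a named clock: intercept, CpG coefficients, output
  transform and native age unit; score-only clocks (epiTOC-style) carry a
  probe set instead of a regression model.
* :class:`CellReference` — probe x cell-type reference methylation profiles
  for blood deconvolution.
* :class:`AgeEstimates` — tidy per-sample, per-clock predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transforms import TransformSpec

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "ClockModel",
    "CellReference",
    "AgeEstimates",
    "ESTIMATE_COLUMNS",
]


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass
class BetaMatrix:
    """CpG-probe x sample matrix of methylation beta values.

    Parameters
    ----------
    values
        DataFrame with probe identifiers as the index and sample identifiers
        as columns.  Entries are floats in [0, 1]; ``NaN`` marks a missing
        measurement.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        df = df.astype(float)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("beta matrix is empty")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        vals = df.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError(
                "beta values outside [0, 1]: "
                f"min={finite.min():.4g}, max={finite.max():.4g}"
            )
        self.values = df

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes) -> "BetaMatrix":
        keep = [p for p in self.values.index if p in set(probes)]
        return BetaMatrix(self.values.loc[keep])

    def __eq__(self, other) -> bool:  # value equality, NaN-aware
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        a, b = self.values, other.values
        return (
            a.index.equals(b.index)
            and a.columns.equals(b.columns)
            and np.array_equal(a.to_numpy(), b.to_numpy(), equal_nan=True)
        )


@dataclass
class SampleSheet:
    """Per-sample annotations: chronological age (years), tissue, group, cohort.

    ``table`` is indexed by sample id with columns ``age_years`` (float,
    non-negative), ``tissue``, ``group`` and ``cohort`` (labels, may be NaN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        for col in ("tissue", "group", "cohort"):
            if col not in df.columns:
                df[col] = pd.Series(pd.NA, index=df.index, dtype="object")
        if "age_years" not in df.columns:
            raise ValidationError("sample sheet lacks an age_years column")
        df["age_years"] = df["age_years"].astype(float)
        ages = df["age_years"].to_numpy()
        if np.any(ages[np.isfinite(ages)] < 0):
            raise ValidationError("negative chronological age")
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def ages(self) -> pd.Series:
        return self.table["age_years"]

    def __len__(self) -> int:
        return len(self.table)


VALID_TRANSFORMS = ("identity", "loglinear", "wu")
VALID_UNITS = ("years", "months")


@dataclass
class ClockModel:
    """A methylation clock: linear predictor over CpG betas plus an output
    transform.

    ``coefficients`` maps probe id -> regression weight; ``intercept`` is the
    constant term.  ``transform`` maps the linear predictor to the clock's
    native age unit (``years`` or ``months``).  Score-only clocks (epiTOC)
    store only a probe set and report the mean beta over it rather than an
    age.
    """

    name: str
    intercept: float | None
    coefficients: dict[str, float]
    transform: TransformSpec
    native_unit: str = "years"
    score_only: bool = False

    def __post_init__(self) -> None:
        if self.native_unit not in VALID_UNITS:
            raise ValidationError(f"unknown native unit {self.native_unit!r}")
        if self.score_only:
            if not self.coefficients:
                raise ValidationError("score-only clock with empty probe set")
        else:
            if self.intercept is None:
                raise ValidationError(f"clock {self.name!r} lacks an intercept")
            self.intercept = float(self.intercept)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    @property
    def probe_set(self) -> set[str]:
        return set(self.coefficients)


@dataclass
class CellReference:
    """Reference methylation profiles for cell-type deconvolution.

    ``profiles`` is a probe x cell-type DataFrame of reference betas in
    [0, 1]; the nominal column set is the six major blood populations
    (CD8 T, CD4 T, NK, B, monocytes, granulocytes), but any panel works.
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.profiles.astype(float)
        if df.columns.has_duplicates:
            raise ValidationError("duplicate cell-type labels")
        if df.index.has_duplicates:
            raise ValidationError("duplicate probe ids in reference")
        vals = df.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("reference betas outside [0, 1]")
        self.profiles = df

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.profiles.index)


#: Column schema of the tidy AgeEstimates table.
ESTIMATE_COLUMNS = [
    "sample_id",
    "clock",
    "native_value",
    "methylation_age_years",
    "chronological_age_years",
    "acceleration_years",
    "score",
    "probe_coverage",
]


@dataclass
class AgeEstimates:
    """Tidy per-sample, per-clock age estimates.

    One row per sample x clock with columns :data:`ESTIMATE_COLUMNS`.
    ``methylation_age_years`` is always in years (months-native clocks are
    converted at this boundary); ``acceleration_years`` is methylation age
    minus chronological age and is missing when the chronological age is
    unknown; ``score`` is populated only for score-only clocks.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"estimate table lacks columns {missing}")
        for col in ESTIMATE_COLUMNS:
            if col not in ("sample_id", "clock"):
                df[col] = df[col].astype(float)
        # acceleration must agree with its definition wherever both ages exist
        both = df["methylation_age_years"].notna() & df[
            "chronological_age_years"
        ].notna()
        if both.any():
            expect = (
                df.loc[both, "methylation_age_years"]
                - df.loc[both, "chronological_age_years"]
            )
            got = df.loc[both, "acceleration_years"]
            if not np.allclose(expect, got, equal_nan=True, atol=1e-9):
                raise ValidationError(
                    "acceleration_years inconsistent with age difference"
                )
        self.table = df.reset_index(drop=True)

    @property
    def clocks(self) -> list[str]:
        return sorted(self.table["clock"].unique())

    def for_clock(self, name: str) -> pd.DataFrame:
        return self.table[self.table["clock"] == name]

    @staticmethod
    def concat(parts: list["AgeEstimates"]) -> "AgeEstimates":
        return AgeEstimates(
            pd.concat([p.table for p in parts], ignore_index=True)
        )
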