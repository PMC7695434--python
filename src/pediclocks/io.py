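"""Readers and writers for beta matrices, sample sheets and clock definitions.

All formats are plain delimited text:

* **Beta matrix** — TSV/CSV in series-matrix orientation: first column probe
  id, header row of sample ids, one row per probe.  Empty fields and ``NA``
  are missing.
* **Sample sheet** — CSV with columns ``sample_id``, ``age_years`` and
  optionally ``tissue``, ``group``, ``cohort``.  Rows without an annotated
  age are dropped (with a logged count), matching the usual exclusion rule
  for public cohorts.
* **Clock definition** — ``#``-prefixed ``key = value`` metadata lines
  (name, transform, anchor, unit, score_only) followed by a two-column
  probe/weight table; the intercept is stored under the reserved probe key
  ``(Intercept)``.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .transforms import TransformSpec
from .types import (
    BetaMatrix,
    CellReference,
    ClockModel,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = ["", "NA", "NaN", "nan"]

INTERCEPT_KEY = "(Intercept)"


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path: str | Path, dialect: str | None = None) -> BetaMatrix:
    """Read a probes x samples beta matrix from delimited text.

    Values must be numeric in [0, 1] or a missing token (empty / ``NA``).
    Duplicate probe or sample ids, non-numeric cells and empty matrices are
    rejected.
    """
    sep = _sep_for(path, dialect)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=MISSING_TOKENS, keep_default_na=False
    )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][~df[col].apply(lambda v: isinstance(v, (int, float)) or pd.isna(v))]
            raise ValidationError(
                f"non-numeric beta values in sample {col!r}: {bad.head(3).tolist()}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path, dialect: str | None = None) -> None:
    sep = _sep_for(path, dialect)
    beta.values.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet CSV; rows lacking an age are dropped with a log."""
    df = pd.read_csv(path, na_values=MISSING_TOKENS, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols:
        raise ValidationError("sample sheet lacks a sample_id column")
    age_col = next((cols[c] for c in ("age_years", "age") if c in cols), None)
    if age_col is None:
        raise ValidationError("sample sheet lacks an age column")
    df = df.rename(columns={cols["sample_id"]: "sample_id", age_col: "age_years"})
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    n_missing = int(df["age_years"].isna().sum())
    if n_missing:
        logger.warning(
            "dropping %d sample(s) without annotated age from %s", n_missing, path
        )
        df = df[df["age_years"].notna()]
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="")


def read_clock_model(path: str | Path) -> ClockModel:
    """Parse a clock-definition file into a :class:`ClockModel`."""
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    header_skipped = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip().lower()] = val.strip()
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip() != ""]
            if len(parts) == 1:
                parts = line.split()
            if not header_skipped and parts and parts[0].lower() in ("probe_id", "probe", "cpg"):
                header_skipped = True
                continue
            if len(parts) < 2:
                raise ValidationError(f"malformed coefficient line: {line!r}")
            try:
                rows.append((parts[0], float(parts[1])))
            except ValueError as exc:
                raise ValidationError(f"non-numeric weight in line {line!r}") from exc

    name = meta.get("name", Path(path).stem)
    kind = meta.get("transform", "identity").lower()
    if kind not in ("identity", "loglinear", "wu"):
        raise ValidationError(f"unknown transform {kind!r} in clock {name!r}")
    anchor = float(meta["anchor"]) if "anchor" in meta else None
    if kind == "wu" and anchor is None:
        anchor = 48.0
    if kind == "loglinear" and anchor is None:
        anchor = 20.0
    unit = meta.get("unit", "months" if kind == "wu" else "years").lower()
    score_only = meta.get("score_only", "false").lower() in ("true", "1", "yes")

    coeffs = {}
    intercept = None
    for probe, weight in rows:
        if probe == INTERCEPT_KEY:
            intercept = weight
        else:
            if probe in coeffs:
                raise ValidationError(f"duplicate probe {probe!r} in clock {name!r}")
            coeffs[probe] = weight
    return ClockModel(
        name=name,
        intercept=intercept,
        coefficients=coeffs,
        transform=TransformSpec(kind, anchor if kind != "identity" else None),
        native_unit=unit,
        score_only=score_only,
    )


def write_clock_model(clock: ClockModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name = {clock.name}\n")
        fh.write(f"# transform = {clock.transform.kind}\n")
        if clock.transform.anchor is not None:
            fh.write(f"# anchor = {clock.transform.anchor:g}\n")
        fh.write(f"# unit = {clock.native_unit}\n")
        fh.write(f"# score_only = {str(clock.score_only).lower()}\n")
        fh.write("probe_id\tweight\n")
        if clock.intercept is not None:
            fh.write(f"{INTERCEPT_KEY}\t{clock.intercept:.12g}\n")
        for probe, w in clock.coefficients.items():
            fh.write(f"{probe}\t{w:.12g}\n")


def bundled_clock_names() -> list[str]:
    """Names of the clock-definition files shipped with the package."""
    pkg = resources.files("pediclocks") / "data"
    return sorted(p.name[: -len(".clock")] for p in pkg.iterdir() if p.name.endswith(".clock"))


def load_bundled_clock(name: str) -> ClockModel:
    """Load a clock definition shipped as package data by name."""
    pkg = resources.files("pediclocks") / "data" / f"{name}.clock"
    with resources.as_file(pkg) as path:
        return read_clock_model(path)


def read_cell_reference(path: str | Path, dialect: str | None = None) -> CellReference:
    """Read a probe x cell-type reference profile matrix."""
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=MISSING_TOKENS, keep_default_na=False)
    df.index = df.index.astype(str)
    return CellReference(df.astype(float))


def write_cell_reference(ref: CellReference, path: str | Path) -> None:
    sep = _sep_for(path, None)
    ref.profiles.to_csv(path, sep=sep, float_format="%.10g")


def read_probe_list(path: str | Path) -> set[str]:
    """Read a mask file: one probe id per line, ``#`` comments allowed."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
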