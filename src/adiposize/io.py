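"""Readers, writers, and validation for the pipeline's CSV tables.

The canonical per-cell table is long form with columns
``subject_id, depot, method, size_parameter, value, unit``; a wide form
(one column per size parameter) is accepted on read and melted.  Depot and
method labels are normalized case-insensitively.  Malformed rows are
rejected with their row numbers so problems in hand-assembled tables are
actionable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SIZE_PARAMETERS, PARAMETER_UNITS, ValidationError

__all__ = [
    "read_cells",
    "read_phenotypes",
    "read_respirometry",
    "write_table",
    "CELL_COLUMNS",
]

logger = logging.getLogger(__name__)

CELL_COLUMNS = ["subject_id", "depot", "method", "size_parameter", "value", "unit"]
DEPOTS = ("sc", "vc")
METHODS = ("histology", "collagenase")
PHENOTYPE_COLUMNS = [
    "subject_id", "age", "sex", "bmi", "t2d", "glucose", "hba1c",
    "cholesterol", "ldl", "hdl", "triglycerides",
]
RESPIROMETRY_COLUMNS = ["subject_id", "depot", "free_oxphos", "oxphos", "ets", "leak"]


def _reject(problems: list[str], what: str) -> None:
    if problems:
        shown = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        raise ValidationError(f"invalid {what}: {shown}{more}")


def _normalize_enum(series: pd.Series, allowed: tuple, name: str) -> pd.Series:
    norm = series.astype(str).str.strip().str.lower()
    bad = ~norm.isin(allowed)
    _reject(
        [f"row {i}: unknown {name} {series.iloc[j]!r}"
         for j, i in enumerate(series.index) if bad.iloc[j]][:20],
        name,
    )
    return norm


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-cell size table (long or wide form).

    Long form requires the canonical columns; wide form requires
    ``subject_id, depot, method`` plus one column per size parameter, and is
    melted to long form with the parameter's standard unit attached.  Values
    must be positive and finite; offending rows are reported by index.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cell table not found: {path}")
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"size_parameter", "value"} <= cols:
        missing = [c for c in CELL_COLUMNS if c not in cols and c != "unit"]
        if missing:
            raise ValidationError(f"cell table missing column(s) {missing}")
        if "unit" not in cols:
            df["unit"] = df["size_parameter"].map(PARAMETER_UNITS)
        long = df[CELL_COLUMNS].copy()
    else:
        required = {"subject_id", "depot", "method"}
        missing = sorted(required - cols)
        if missing:
            raise ValidationError(f"cell table missing column(s) {missing}")
        params = [p for p in SIZE_PARAMETERS if p in cols]
        if not params:
            raise ValidationError(
                f"wide cell table needs at least one of {SIZE_PARAMETERS}"
            )
        long = df.melt(
            id_vars=["subject_id", "depot", "method"],
            value_vars=params,
            var_name="size_parameter",
            value_name="value",
        ).dropna(subset=["value"])
        long["unit"] = long["size_parameter"].map(PARAMETER_UNITS)

    long["depot"] = _normalize_enum(long["depot"], DEPOTS, "depot")
    long["method"] = _normalize_enum(long["method"], METHODS, "method")
    bad_param = ~long["size_parameter"].isin(SIZE_PARAMETERS)
    _reject(
        [f"row {i}: unknown size_parameter {long['size_parameter'].loc[i]!r}"
         for i in long.index[bad_param][:20]],
        "size_parameter",
    )
    values = pd.to_numeric(long["value"], errors="coerce")
    bad_val = ~np.isfinite(values) | (values <= 0)
    _reject(
        [f"row {i}: non-positive or non-numeric value {long['value'].loc[i]!r}"
         for i in long.index[bad_val][:20]],
        "value",
    )
    long["value"] = values
    logger.info("read_cells: %d records from %s", len(long), path)
    return long.reset_index(drop=True)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the subject phenotype table; any variable may be missing per row."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValidationError("phenotype table missing column 'subject_id'")
    problems = []
    for col in ("bmi",):
        if col in df.columns:
            bad = df[col].notna() & (pd.to_numeric(df[col], errors="coerce") <= 0)
            problems += [f"row {i}: non-positive {col}" for i in df.index[bad][:20]]
    for col, allowed in (("sex", ("female", "male")), ("t2d", ("yes", "no", "unknown"))):
        if col in df.columns:
            present = df[col].notna()
            norm = df.loc[present, col].astype(str).str.strip().str.lower()
            bad = ~norm.isin(allowed)
            problems += [f"row {i}: invalid {col} {df[col].loc[i]!r}"
                         for i in norm.index[bad][:20]]
            df.loc[present, col] = norm
    _reject(problems, "phenotype table")
    return df


def read_respirometry(path: str | Path) -> pd.DataFrame:
    """Read the respirometry table (states in pmol O2 / (s * ng DNA))."""
    df = pd.read_csv(path)
    missing = [c for c in RESPIROMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"respirometry table missing column(s) {missing}")
    df["depot"] = _normalize_enum(df["depot"], DEPOTS, "depot")
    problems = []
    for col in RESPIROMETRY_COLUMNS[2:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & (~np.isfinite(vals) | (vals < 0))
        problems += [f"row {i}: negative or non-numeric {col}" for i in df.index[bad][:20]]
        df[col] = vals
    _reject(problems, "respirometry table")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV, excluding generator-internal columns (leading underscore)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    public = df[[c for c in df.columns if not str(c).startswith("_")]]
    public.to_csv(path, index=False)
    return path
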