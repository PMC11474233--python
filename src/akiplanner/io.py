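"""Cohort CSV schema, validated readers/writers and JSON report export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    EXTENDED_FEATURES,
    GROUP_NEG,
    GROUP_POS,
    PLAN_PARAMS,
    PREOP_FEATURES,
)

__all__ = ["SchemaError", "read_cohort_csv", "write_cohort_csv", "write_report"]

REQUIRED_COLUMNS = ["PatientID", *PREOP_FEATURES, *PLAN_PARAMS, "Cr_day1", "Cr_day7"]
OPTIONAL_COLUMNS = [*EXTENDED_FEATURES, "Group", "Stage_day1", "Stage_day7"]
NON_NUMERIC = {"PatientID", "Group"}


class SchemaError(ValueError):
    """Raised when a cohort CSV does not match the expected schema."""


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Unknown columns and non-numeric cells are hard errors (reported with
    their location); missing cells are empty fields and load as NaN.  An
    empty file is a schema error, not an empty cohort.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file (no header row)") from None
    if df.empty and len(df.columns) == 0:
        raise SchemaError(f"{path}: empty file")

    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"{path}: unknown columns {unknown}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    out = pd.DataFrame()
    out["PatientID"] = df["PatientID"]
    for col in df.columns:
        if col in NON_NUMERIC:
            out[col] = df[col].replace("", np.nan)
            continue
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce").astype(float)
        bad = vals.isna() & (raw != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        out[col] = vals
    if "Group" in out.columns:
        bad_groups = set(out["Group"].dropna().unique()) - {GROUP_POS, GROUP_NEG}
        if bad_groups:
            raise SchemaError(f"{path}: invalid group labels {sorted(bad_groups)}")
    return out[list(df.columns)]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV with missing cells as empty fields."""
    cohort.to_csv(path, index=False, float_format="%.10g", na_rep="")


def write_report(report: dict, path) -> None:
    """Write a JSON report deterministically (sorted keys, fixed layout)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
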