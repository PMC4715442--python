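"""Reading and writing response matrices and result tables.

The on-disk format for a response matrix is a plain CSV with a header:
``respondent_id, age, sex, item_1 ... item_20``; item cells hold integer
codes 0-3 or a missing marker (empty cell or ``NA``).  Validation reports
malformed codes with row and column so data problems are actionable.
Writes go through a temp file and are moved into place only on success,
so a failed run never leaves a partial table behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import item_columns

__all__ = ["read_responses", "write_responses", "atomic_write_csv", "ValidationError"]

MISSING_MARKERS = {"", "NA", "na", "NaN", "nan"}


class ValidationError(ValueError):
    """Input file fails structural or code validation."""


def read_responses(path) -> pd.DataFrame:
    """Read and validate a respondent-level response matrix CSV.

    Missing markers are normalized to NaN; rows with missing values are
    retained (exclusions handle them downstream).  Non-integer or
    out-of-range codes raise :class:`ValidationError` naming the first
    offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cannot read {path}: no such file")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["age"] + item_columns()
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {missing_cols}")
    if "respondent_id" not in df.columns:
        df.insert(0, "respondent_id", np.arange(len(df)))
    if "sex" not in df.columns:
        df["sex"] = ""

    def _to_num(col: str, valid: set[int] | None) -> pd.Series:
        raw = df[col].str.strip()
        out = pd.Series(np.nan, index=df.index, dtype=float)
        present = ~raw.isin(MISSING_MARKERS)
        vals = pd.to_numeric(raw[present], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValidationError(f"{path}: non-numeric value in column {col}, line {row}")
        if valid is not None:
            outside = ~vals.isin(list(valid))
            if outside.any():
                row = int(outside.idxmax()) + 2
                v = vals[outside].iloc[0]
                raise ValidationError(
                    f"{path}: invalid code {v:g} in column {col}, line {row} "
                    f"(expected one of {sorted(valid)})"
                )
        out[present] = vals
        return out

    df["age"] = _to_num("age", None)
    for c in item_columns():
        df[c] = _to_num(c, {0, 1, 2, 3})
    return df


def atomic_write_csv(df: pd.DataFrame, path, **kwargs) -> None:
    """Write a CSV via a temp file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, index=False, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_responses(df: pd.DataFrame, path) -> None:
    """Write a response matrix CSV (integer codes, NA for missing)."""
    out = df.copy()
    for c in item_columns():
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["age"] = out["age"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    atomic_write_csv(out, path)
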