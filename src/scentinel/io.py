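"""Cohort file I/O with row-level validation.

The cohort file is UTF-8 CSV with a fixed, ordered header::

    subject_id,group,age,sex,ethnicity_white,detect_correct,intensity,
    id1_correct,id2_correct,nih_item_1,...,nih_item_9

Booleans are encoded 0/1; structural missingness (second identification
attempt not offered, reference test not taken) is an empty string, never a
sentinel number.  Every row must pass response validation on load: intensity
in [0, 100], and the second identification attempt present exactly when the
first failed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from scentinel.cohort import COHORT_COLUMNS

PathLike = Union[str, Path, _io.IOBase]


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based file line number (header = line 1)
    message: str


class CohortValidationError(ValueError):
    def __init__(self, errors: list[RowError]):
        self.errors = errors
        lines = "; ".join(f"line {e.line}: {e.message}" for e in errors[:10])
        more = f" (+{len(errors) - 10} more)" if len(errors) > 10 else ""
        super().__init__(f"cohort validation failed: {lines}{more}")


def _validate_rows(df: pd.DataFrame) -> list[RowError]:
    errors: list[RowError] = []
    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        if not 0 <= row["intensity"] <= 100:
            errors.append(RowError(line, f"intensity {row['intensity']} outside [0, 100]"))
        id1 = row["id1_correct"] == 1
        id2_present = pd.notna(row["id2_correct"])
        if id1 and id2_present:
            errors.append(
                RowError(line, "second identification present despite correct first attempt")
            )
        if not id1 and not id2_present:
            errors.append(
                RowError(line, "second identification missing after failed first attempt")
            )
        if row["group"] not in ("anosmic", "other", "normosmic") and pd.notna(row["group"]):
            errors.append(RowError(line, f"unknown group {row['group']!r}"))
        if row["sex"] not in ("F", "M", "unreported"):
            errors.append(RowError(line, f"unknown sex {row['sex']!r}"))
        items = row[[f"nih_item_{j}" for j in range(1, 10)]]
        if items.notna().any() and not items.notna().all():
            errors.append(RowError(line, "partial reference-test items"))
    return errors


def read_cohort(path: PathLike, strict: bool = True) -> pd.DataFrame:
    """Load and validate a cohort CSV.

    In strict mode any invalid row raises :class:`CohortValidationError`
    listing offending line numbers; otherwise invalid rows are dropped and
    the errors attached to ``df.attrs['row_errors']``.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "group": str, "sex": str},
    )
    if list(df.columns) != COHORT_COLUMNS:
        raise ValueError(
            f"malformed header: expected {COHORT_COLUMNS}, got {list(df.columns)}"
        )
    for col in ("age", "intensity"):
        if not np.issubdtype(df[col].dtype, np.integer):
            as_float = df[col].astype(float)
            if not np.allclose(as_float, np.round(as_float)):
                raise ValueError(f"non-integer values in column {col!r}")
            df[col] = as_float.astype(int)
    errors = _validate_rows(df)
    if errors:
        if strict:
            raise CohortValidationError(errors)
        bad_lines = {e.line for e in errors}
        df = df[~(df.index + 2).isin(bad_lines)].reset_index(drop=True)
        df.attrs["row_errors"] = errors
    return df


def write_cohort(df: pd.DataFrame, path: PathLike) -> None:
    """Write a cohort table in the canonical column order, 0/1 booleans and
    empty-string missingness; ``write_cohort`` then ``read_cohort`` is the
    identity on valid cohorts."""
    out = df[COHORT_COLUMNS].copy()
    for col in ["id2_correct"] + [f"nih_item_{j}" for j in range(1, 10)]:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)
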