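"""Count-table and result I/O with strict schema validation.

Count tables are tidy UTF-8 CSV with a mandatory header and columns
``animal_id, region, stage, n_gfp_pos, n_gfp_neg`` (an optional leading
``cohort`` column is preserved).  Counts must be non-negative integers;
malformed rows are reported with their file line numbers and the offending
field.  ``read(write(x))`` is the identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import COUNT_COLUMNS

__all__ = [
    "read_count_table",
    "write_count_table",
    "write_estimates",
    "read_trajectory_table",
    "write_trajectory_table",
]

COUNT_FIELDS = ("n_gfp_pos", "n_gfp_neg")
PCT_COLUMNS = ("mean_gfp_pct", "sem_gfp_pct")


def _validate_counts(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    for col in COUNT_FIELDS:
        values = pd.to_numeric(df[col], errors="coerce")
        # header is line 1, first data row line 2
        bad_parse = df.index[values.isna()] + 2
        if len(bad_parse):
            raise SchemaError(
                f"{source}: column {col!r} has non-numeric values on line(s) "
                f"{list(bad_parse)}"
            )
        non_integral = df.index[(values % 1) != 0] + 2
        if len(non_integral):
            raise SchemaError(
                f"{source}: column {col!r} has non-integer counts on line(s) "
                f"{list(non_integral)}"
            )
        negative = df.index[values < 0] + 2
        if len(negative):
            raise SchemaError(
                f"{source}: column {col!r} has negative counts on line(s) "
                f"{list(negative)}"
            )
        df[col] = values.astype(np.int64)
    for col in ("animal_id", "region", "stage"):
        df[col] = df[col].astype(str)
    if "cohort" in df.columns:
        df["cohort"] = df["cohort"].astype(str)
        df = df[["cohort", *COUNT_COLUMNS]]
    else:
        df = df[list(COUNT_COLUMNS)]
    return df


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell-count CSV; empty files with a header are fine."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file has no header row") from exc
    return _validate_counts(df, str(path))


def write_count_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a count table as UTF-8 CSV with a header row."""
    table.to_csv(path, index=False, encoding="utf-8")


def write_estimates(path: str | Path, estimates: pd.DataFrame, decimals: int = 1) -> None:
    """Write a per-group estimate table; percentage columns are rounded to
    ``decimals`` places (display convention: one decimal)."""
    out = estimates.copy()
    for col in PCT_COLUMNS:
        if col in out.columns:
            out[col] = out[col].round(decimals)
    out.to_csv(path, index=False, encoding="utf-8")


def read_trajectory_table(path: str | Path) -> pd.DataFrame:
    """Read a per-stage trajectory CSV (stage, gfp_fraction_mean,
    gfp_fraction_sem, n_animals)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"stage", "gfp_fraction_mean", "gfp_fraction_sem", "n_animals"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def write_trajectory_table(path: str | Path, traj) -> None:
    frame = traj.to_frame() if hasattr(traj, "to_frame") else traj
    frame.to_csv(path, index=False, encoding="utf-8")
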