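"""Reading, writing and validation of the pipeline's tabular formats.

All tables are TSV (UTF-8, header row, "." decimal) to avoid CSV
decimal-separator ambiguity. Tract, metric and categorical vocabularies are
closed lists validated on read; required columns may not contain NA.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tracts import GROUPS, METRIC_SET, SCANNERS, SEXES, TRACT_SET, RISK_FACTORS

__all__ = [
    "ValidationError",
    "read_long_table",
    "write_long_table",
    "read_risk_table",
    "write_risk_table",
    "read_brain_matrix",
    "write_brain_matrix",
    "file_checksum",
]

LONG_COLUMNS = [
    "subject_id", "group", "sex", "scanner",
    "visit_index", "age", "tract", "metric", "value",
]


class ValidationError(ValueError):
    """Input table violates the schema or its invariants."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def _check_vocab(df: pd.DataFrame, column: str, allowed, path) -> None:
    bad = sorted(set(df[column].unique()) - set(allowed))
    if bad:
        rows = df.index[df[column].isin(bad)][:5].tolist()
        raise ValidationError(
            f"{path}: invalid {column} value(s) {bad} (e.g. rows {rows}); "
            f"allowed: {sorted(allowed)}"
        )


def validate_long_table(df: pd.DataFrame, path="<table>") -> pd.DataFrame:
    """Validate and normalize a long metric table (see LONG_COLUMNS)."""
    _require_columns(df, LONG_COLUMNS, path)
    df = df[LONG_COLUMNS].copy()
    if df[LONG_COLUMNS].isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise ValidationError(f"{path}: NA in required columns (e.g. rows {bad})")
    df["visit_index"] = df["visit_index"].astype(int)
    df["age"] = df["age"].astype(float)
    df["value"] = df["value"].astype(float)
    for col in ("subject_id", "group", "sex", "scanner", "tract", "metric"):
        df[col] = df[col].astype(str)
    _check_vocab(df, "group", GROUPS, path)
    _check_vocab(df, "sex", SEXES, path)
    _check_vocab(df, "scanner", SCANNERS, path)
    _check_vocab(df, "tract", TRACT_SET, path)
    _check_vocab(df, "metric", METRIC_SET, path)

    keys = df[["subject_id", "visit_index", "tract", "metric"]]
    dup = keys.duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (subject, visit, tract, metric) keys "
            f"(e.g. rows {df.index[dup][:5].tolist()})"
        )
    visits = df.drop_duplicates(["subject_id", "visit_index"])[
        ["subject_id", "visit_index", "age"]
    ]
    # one age per (subject, visit) across all tract/metric rows
    n_ages = df.groupby(["subject_id", "visit_index"])["age"].nunique()
    if (n_ages > 1).any():
        bad = n_ages.index[n_ages > 1][:5].tolist()
        raise ValidationError(f"{path}: inconsistent ages within visits {bad}")
    for sid, sub in visits.sort_values("visit_index").groupby("subject_id"):
        if not np.all(np.diff(sub["age"].to_numpy()) > 0):
            raise ValidationError(
                f"{path}: ages not strictly increasing with visit_index for {sid}"
            )
    return df


def read_long_table(path) -> pd.DataFrame:
    """Read and validate a long metric table TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return validate_long_table(df, path)


def write_long_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_risk_table(path) -> pd.DataFrame:
    """Read and validate the per-subject dichotomized risk-factor table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["subject_id", *RISK_FACTORS], path)
    df = df[["subject_id", *RISK_FACTORS]].copy()
    if df.isna().any().any():
        raise ValidationError(f"{path}: NA entries in risk-factor table")
    df["subject_id"] = df["subject_id"].astype(str)
    for rf in RISK_FACTORS:
        vals = set(pd.unique(df[rf]))
        if not vals <= {0, 1}:
            raise ValidationError(f"{path}: {rf} must be binary 0/1, got {sorted(vals)}")
        df[rf] = df[rf].astype(int)
    if df["subject_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate subject_id in risk-factor table")
    return df


def write_risk_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_brain_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    if df.isna().any().any():
        raise ValidationError(f"{path}: NA cells in brain matrix")
    return df.astype(float)


def write_brain_matrix(X: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index=True, index_label="subject_id")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
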