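"""TSV readers/writers with light schema validation.

All pipeline tables are tab-separated with a header row; matrices carry
probe or sample identifiers in the first column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "read_kinship",
    "read_annotation",
    "read_modules",
    "SchemaError",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "family_id", "age", "sex", "center", "smoking", "logTG"]
ANNOTATION_COLUMNS = ["probe_id", "gene"]
MODULE_COLUMNS = ["probe_id", "module"]


class SchemaError(ValueError):
    """A TSV file does not match its documented schema."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns {missing}")


def read_matrix(path: str | Path, index_name: str = "probe_id") -> pd.DataFrame:
    """Read a values matrix (rows indexed by the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.shape[1] == 0:
        raise SchemaError(f"{path}: empty matrix")
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label or df.index.name or "id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SAMPLE_SHEET_COLUMNS, "sample sheet")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_kinship(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1] or not (df.index == df.columns).all():
        raise SchemaError("kinship matrix must be square with matching row/column ids")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ANNOTATION_COLUMNS, "probe annotation")
    return df


def read_modules(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, MODULE_COLUMNS, "module table")
    return pd.Series(df["module"].to_numpy(), index=df["probe_id"], name="module")
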