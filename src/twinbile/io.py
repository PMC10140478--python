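"""Tabular readers and writers.

All tables are TSV (CSV accepted on read, sniffed from the extension or
delimiter). Matrices are samples x features with the id in the first
column; an empty cell is a missing value. Output tables carry reproducibility
metadata (seed, input checksums) as ``# key: value`` comment lines, which
readers skip.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_matrix", "write_matrix", "read_metadata", "write_table", "sha256_of"]

METADATA_COLUMNS = ("sample_id", "family_id", "zygosity", "age", "bmi", "sex", "cohort")


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def read_matrix(path: str | Path, orientation: str = "wide") -> pd.DataFrame:
    """Read a samples x features matrix.

    ``orientation='wide'`` expects an id column followed by one column per
    feature; ``'long'`` expects three columns (sample, feature, value) and
    pivots to the same wide layout. Duplicate ids and ragged rows are
    errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep(path), comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path.name}: {exc}") from exc
    if orientation == "long":
        if df.shape[1] != 3:
            raise ValueError("long format needs exactly 3 columns")
        sample_col, feat_col, val_col = df.columns
        dup = df.duplicated([sample_col, feat_col])
        if dup.any():
            raise ValueError(f"duplicate (sample, feature) pair at row {int(dup.idxmax())}")
        wide = df.pivot(index=sample_col, columns=feat_col, values=val_col)
        wide.index.name = sample_col
        wide.columns.name = None
        return wide
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dup_id = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup_id!r}")
    return df


def write_matrix(
    df: pd.DataFrame, path: str | Path, header_meta: dict | None = None
) -> None:
    """Write a wide matrix as TSV; missing values become empty cells."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep=_sep(path), na_rep="")


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    missing = {"sample_id", "family_id", "zygosity"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep=_sep(path), na_rep="", index=False)
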