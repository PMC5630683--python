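"""Tabular IO: count matrices and sample metadata as TSV."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .features import CountMatrix, METADATA_COLUMNS


def read_counts(path: str | Path) -> pd.DataFrame:
    """Counts TSV: rows are feature ids, columns are sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in count matrix")
    return df.astype(int)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Metadata TSV with the fixed header, indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"stage": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return df.set_index("sample_id")


def read_count_matrix(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_metadata(metadata_path))


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("feature_id").to_csv(path, sep="\t")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample_id").reset_index()[list(METADATA_COLUMNS)].to_csv(
        path, sep="\t", index=False
    )
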