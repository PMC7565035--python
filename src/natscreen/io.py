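"""TSV readers and writers for cohort files.

All tabular I/O is tab-separated with a single header line; matrices are
genes/probes as rows and samples as columns. Floats are written with
pandas' default full-precision repr so a write/read cycle is lossless.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing matrix file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated row ids in {path.name}: {dupes}")
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing table file: {path}")
    return pd.read_csv(path, sep="\t")
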