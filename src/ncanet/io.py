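"""Tab-separated I/O for expression matrices, label files and matrix dumps.

The canonical in-memory container throughout the package is a pandas
DataFrame with gene identifiers as the index and sample identifiers as the
columns (genes x samples). Labels are a pandas Series indexed by sample id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    The first column holds gene identifiers, the header row sample ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.12g")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, stage) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"label file {path} must have exactly two columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="stage")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample_id": labels.index, "stage": labels.values}).to_csv(
        path, sep="\t", index=False
    )


def write_matrix(
    values: np.ndarray, rows, cols, path: str | Path, index_label: str = "id"
) -> None:
    """Dump a labelled numeric matrix as TSV (12 significant digits)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(values, index=rows, columns=cols).to_csv(
        path, sep="\t", index_label=index_label, float_format="%.12g"
    )


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
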