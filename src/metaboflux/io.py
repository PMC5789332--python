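"""TSV readers/writers for expression matrices and sample designs.

An expression (or raw signal) matrix is a :class:`pandas.DataFrame` with
gene/probe identifiers as the index and sample identifiers as columns.
The companion design maps each sample to its treatment group and is
carried as a :class:`pandas.Series` indexed by sample id.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_signal_tsv",
    "write_signal_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "validate_matrix",
]


def read_signal_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample intensity table (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_signal_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_design_tsv(path: str | Path) -> pd.Series:
    """Read a ``sample_id<TAB>group`` table into a sample->group Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(
            f"design file {path} must have columns sample_id, group; got {list(df.columns)}"
        )
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def write_design_tsv(design: pd.Series, path: str | Path) -> None:
    out = pd.DataFrame({"sample_id": design.index, "group": design.values})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def validate_matrix(matrix: pd.DataFrame, design: pd.Series | None = None) -> None:
    """Check the core invariants: finite non-negative values, samples in design."""
    import numpy as np

    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("intensity matrix contains non-finite entries")
    if (values < 0).any():
        raise ValueError("intensity matrix contains negative entries")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene labels: {dupes}")
    if design is not None:
        missing = [s for s in matrix.columns if s not in design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
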