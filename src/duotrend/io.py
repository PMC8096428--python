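"""Reading and writing the delimited tables the pipeline touches.

On-disk convention: features in rows, samples in columns, one header row of
sample IDs and one leading column of feature IDs.  The delimiter is taken
from the extension (.tsv -> tab, .csv -> comma); the decimal separator is
always a point.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_expression_table", "read_metadata", "write_table", "FLOAT_FORMAT"]

#: fixed float formatting: full double precision (lossless round-trip) and
#: locale-independent, so identical runs produce byte-identical files
FLOAT_FORMAT = "%.17g"


def _sep_for(path: Path) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = sorted(index[index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what} IDs: {dups}")


def read_expression_table(path, features_in_rows: bool = True) -> pd.DataFrame:
    """Read a delimited expression table into a features x samples DataFrame.

    Feature and sample IDs must be unique; every data cell must parse as a
    number (a parse failure is reported with its row/column coordinates).
    Missing cells are kept as NaN — flagged via ``df.attrs['n_missing']`` —
    never silently zeroed.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "feature" if features_in_rows else "sample")
    _check_unique(pd.Index(raw.columns), "sample" if features_in_rows else "feature")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {raw.index[r]!r}, column {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    # re-read numerically with exactly-rounding parsing (the string pass above
    # was only for duplicate/non-numeric diagnostics)
    numeric = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                          float_precision="round_trip")
    numeric.index = numeric.index.astype(str)
    if not features_in_rows:
        numeric = numeric.T
    numeric.attrs["n_missing"] = int(numeric.isna().sum().sum())
    return numeric


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata table (sample IDs in the first column)."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                       float_precision="round_trip")
    meta.index = meta.index.astype(str)
    _check_unique(meta.index, "sample")
    return meta


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a table with the extension-matched delimiter and fixed float format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=index, float_format=FLOAT_FORMAT)
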