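"""Reading raw samples from plain-text files.

Two layouts are accepted: a bare vector (one numeric value per line) and a
delimited table with a value column and a group column.  Non-numeric rows
are rejected with the offending row named — never skipped silently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["load_vector", "load_grouped_table"]


def load_vector(path: str | Path) -> np.ndarray:
    """Read one numeric value per line."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError:
                raise ValueError(f"{path}: non-numeric value {s!r} on line {lineno}")
    if not values:
        raise ValueError(f"{path}: no values")
    return np.asarray(values, dtype=float)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def load_grouped_table(
    path: str | Path,
    value_column: str,
    group_column: str,
    groups: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, np.ndarray, Tuple[str, str]]:
    """Split a CSV/TSV table into two numeric sample vectors.

    ``groups`` selects and orders the two labels to compare; without it the
    table must contain exactly two distinct labels (ordered as first
    encountered).  Returns (values1, values2, (label1, label2)).
    """
    df = _read_table(path)
    for col in (value_column, group_column):
        if col not in df.columns:
            raise ValueError(f"{path}: no column {col!r} (have {list(df.columns)})")
    labels = list(dict.fromkeys(df[group_column].astype(str)))
    if groups is None:
        if len(labels) != 2:
            raise ValueError(
                f"{path}: need exactly 2 group labels, found {len(labels)}: {labels}; "
                "select a pair explicitly"
            )
        groups = labels
    else:
        groups = [str(g) for g in groups]
        if len(groups) != 2:
            raise ValueError("exactly two group labels must be selected")
        missing = [g for g in groups if g not in labels]
        if missing:
            raise ValueError(f"{path}: group label(s) not present: {missing}")

    out = []
    for label in groups:
        sub = df.loc[df[group_column].astype(str) == label, value_column]
        if sub.empty:
            raise ValueError(f"{path}: group {label!r} is empty")
        vals = pd.to_numeric(sub, errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # +header, 1-based
            raise ValueError(f"{path}: non-numeric value in row {row}")
        out.append(vals.to_numpy(dtype=float))
    return out[0], out[1], (groups[0], groups[1])
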