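"""Embedded example data.

The package ships Fisher's (1936) Iris measurements — 50 flowers of each of
three species, four lengths in centimetres — as a worked heteroscedastic
example: the species have clearly unequal spreads, so the pooled-SD and
Welch-based effect sizes can be compared measurement by measurement.

The embedded copy follows Fisher's printed table.  It differs from the
variant shipped with R/UCI in three setosa cells (flower 35 petal width
0.1 vs 0.2; flower 38 sepal width 3.6 vs 3.1 and petal length 1.4 vs 1.5,
a long-documented transcription discrepancy between the two sources).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["iris", "iris_group", "MEASUREMENTS", "SPECIES"]

MEASUREMENTS = ("sepal_length", "sepal_width", "petal_length", "petal_width")
SPECIES = ("setosa", "versicolor", "virginica")


def iris() -> pd.DataFrame:
    """The 150-flower Iris table: species plus four measurements (cm)."""
    with resources.files("meandiff.data").joinpath("iris.csv").open("r") as fh:
        return pd.read_csv(fh)


def iris_group(species: str, measurement: str) -> np.ndarray:
    """One species' 50 values of one measurement."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    if measurement not in MEASUREMENTS:
        raise ValueError(f"unknown measurement {measurement!r}")
    df = iris()
    return df.loc[df["species"] == species, measurement].to_numpy(dtype=float)
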