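"""Plain-text table IO for abundance matrices and flux state tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .omics import AbundanceMatrix

__all__ = ["write_abundance", "read_abundance", "write_table", "read_table"]


def write_abundance(matrix: AbundanceMatrix, values_path, samples_path=None) -> None:
    """Write an abundance matrix as a values CSV plus a sample-group CSV.

    The values CSV is feature_id x sample columns; the companion CSV
    (default ``<values>.samples.csv``) holds sample_id,group,layer.
    """
    values_path = Path(values_path)
    samples_path = Path(samples_path) if samples_path else values_path.with_suffix(
        ".samples.csv"
    )
    matrix.values.to_csv(values_path, index_label="feature_id")
    pd.DataFrame(
        {
            "sample_id": list(matrix.values.columns),
            "group": [matrix.groups[s] for s in matrix.values.columns],
            "layer": matrix.layer,
        }
    ).to_csv(samples_path, index=False)


def read_abundance(values_path, samples_path=None) -> AbundanceMatrix:
    values_path = Path(values_path)
    samples_path = Path(samples_path) if samples_path else values_path.with_suffix(
        ".samples.csv"
    )
    values = pd.read_csv(values_path, index_col="feature_id")
    samples = pd.read_csv(samples_path)
    groups = pd.Series(samples["group"].to_numpy(), index=samples["sample_id"])
    layer = str(samples["layer"].iloc[0]) if "layer" in samples.columns else "protein"
    return AbundanceMatrix(values=values, groups=groups, layer=layer)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
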