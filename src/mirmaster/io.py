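"""TSV readers/writers for the pipeline's table dialect."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: features in rows (first column "feature"), samples in columns."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "feature"
    return df


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
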