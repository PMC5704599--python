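"""Readers/writers for the plain-TSV interchange formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """Feature-by-sample matrix with the feature id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"steer": str, "diet": str})
    return df.set_index("sample_id")


def read_binning(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["contig_id"], df["bin_id"]))
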