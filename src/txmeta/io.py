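"""Plain-text readers and writers for the pipeline's tabular formats.

Everything is tab-separated. Expression tables are genes x samples with the
gene identifier as the row index; metadata tables are samples x fields with
``sample_id`` as the index. Gene identifiers are always read as strings so
that Entrez-style integer IDs survive round trips unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_ortholog_table",
    "write_ortholog_table",
    "read_de_results",
    "write_de_results",
    "write_json",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Read a harmonized-key <-> species-ID mapping table.

    Columns: ``harmonized_key``, ``mouse_entrez``, ``rat_entrez`` and
    optionally ``symbol``. Missing species IDs are empty fields.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"harmonized_key", "mouse_entrez", "rat_entrez"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    return df


def write_ortholog_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_de_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_de_results(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
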