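"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated. The count matrix has ``gene_id`` as its first
column and one integer column per sample; the design table is the per-sample
factor table of :mod:`gravscreen.design`; gene sets use the GMT format
(set name, description, then member gene ids, tab-separated).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

from .design import validate_design


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample count matrix (index: gene_id, int values)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in {path}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return df.astype("int64")


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample real-valued matrix (e.g. normalized values)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype("float64")


def write_matrix(matrix: pd.DataFrame, path: str | os.PathLike, index_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    df["time"] = df["time"].astype("Int64")
    validate_design(df)
    return df


def write_design(design: pd.DataFrame, path: str | os.PathLike) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Generic TSV table reader (used for truth / report tables)."""
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read gene sets from a GMT file; returns name -> member gene ids.

    The description field (second column) is discarded; use
    :func:`read_gmt_with_descriptions` to keep it.
    """
    return {name: members for name, (_, members) in read_gmt_with_descriptions(path).items()}


def read_gmt_with_descriptions(path: str | os.PathLike) -> dict[str, tuple[str, list[str]]]:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, description, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = (description, members)
    return sets


def write_gmt(
    gene_sets: Mapping[str, Iterable[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_panel(path: str | os.PathLike, gmt_set: str | None = None) -> list[str]:
    """Read a gene panel: plain text (one id per line) or a named GMT set."""
    if gmt_set is not None:
        sets = read_gmt(path)
        if gmt_set not in sets:
            raise KeyError(f"gene set {gmt_set!r} not found in {path}")
        return list(sets[gmt_set])
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_panel(panel: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gene in panel:
            fh.write(f"{gene}\n")
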