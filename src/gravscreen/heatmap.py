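"""Log-transformed condition means and three-way regulation grouping.

Per gene and condition the displayed value is ``log2(mean normalized
expression + 0.01)``; each non-reference condition is then allocated to
``no_change`` / ``down`` / ``up`` by comparing its transformed value with
the standing non-irradiated reference: an absolute difference below 1.0
(i.e. less than a two-fold change) is "no change", otherwise the sign
decides. The matrix is written as a viewer-importable TSV (genes as rows,
conditions as columns, fixed condition order).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONDITION_ORDER

__all__ = ["HeatmapMatrix", "transform_values", "allocate_groups", "write_heatmap"]

PSEUDOCOUNT = 0.01
GROUP_DELTA = 1.0

#: Color-scale bounds recorded in exported metadata (down, mid, up).
COLOR_SCALE = (-7.0, 0.0, 13.0)


@dataclass
class HeatmapMatrix:
    values: pd.DataFrame              # genes x conditions, transformed
    groups: pd.DataFrame | None = None  # genes x non-reference conditions
    reference: str = "ST"


def transform_values(
    normalized: pd.DataFrame, design: pd.DataFrame, genes=None
) -> HeatmapMatrix:
    """Transformed value per gene and condition: log2(replicate mean + 0.01)."""
    sub = normalized if genes is None else normalized.loc[list(genes)]
    cond = design.set_index("sample_id")["condition"]
    means = sub.T.groupby(cond).mean().T
    order = [c for c in CONDITION_ORDER if c in means.columns]
    values = np.log2(means[order] + PSEUDOCOUNT)
    return HeatmapMatrix(values=values)


def allocate_groups(matrix: HeatmapMatrix, reference: str = "ST") -> pd.DataFrame:
    """Allocate each gene x non-reference condition to a regulation group.

    delta = transformed(condition) - transformed(reference); |delta| < 1.0
    -> no_change, delta <= -1.0 -> down, delta >= 1.0 -> up (the boundary
    |delta| == 1.0 counts as changed).
    """
    if reference not in matrix.values.columns:
        raise ValueError(f"reference condition {reference!r} not in matrix")
    ref = matrix.values[reference]
    groups = {}
    for c in matrix.values.columns:
        if c == reference:
            continue
        delta = matrix.values[c] - ref
        g = pd.Series("no_change", index=matrix.values.index)
        g[delta <= -GROUP_DELTA] = "down"
        g[delta >= GROUP_DELTA] = "up"
        groups[c] = g
    out = pd.DataFrame(groups)
    matrix.groups = out
    matrix.reference = reference
    return out


def group_counts(groups: pd.DataFrame) -> pd.DataFrame:
    """Per-condition totals of (no_change, down, up) allocations."""
    return groups.apply(lambda col: col.value_counts()).reindex(
        ["no_change", "down", "up"]
    ).fillna(0).astype(int).T


def write_heatmap(
    matrix: HeatmapMatrix, path: str | os.PathLike, groups_path: str | os.PathLike | None = None
) -> None:
    """Write the transformed matrix (and optionally the group allocations)."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if groups_path is not None:
        if matrix.groups is None:
            allocate_groups(matrix)
        matrix.groups.to_csv(groups_path, sep="\t", index_label="gene_id")


def read_heatmap(path: str | os.PathLike) -> HeatmapMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return HeatmapMatrix(values=values)
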