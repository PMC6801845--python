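"""Gene-set over-representation by the hypergeometric upper tail.

Given a query list (e.g. genes up-regulated under simulated microgravity),
each gene set is intersected with the universe (all detected genes by
default) and scored with p = P(X >= overlap) for X ~
Hypergeometric(universe, set, list). This is the plain over-representation
statistic; no service-specific score modifications are applied.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = ["hypergeom_enrich", "top_pathways"]


def hypergeom_enrich(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    bh: bool = False,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each gene set.

    Results are sorted by p-value, ties broken by descending overlap
    fraction. Genes outside the universe are ignored in both the list and
    the sets. ``bh=True`` appends Benjamini-Hochberg adjusted p-values
    across sets.
    """
    universe = set(universe)
    query = set(gene_list) & universe
    if not set(gene_list):
        warnings.warn("empty gene list: returning empty enrichment table", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "set_name", "overlap", "set_size", "list_size",
                "universe_size", "p_value", "members",
            ]
        )
    rows = []
    m = len(universe)
    n = len(query)
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(members & query)
        # P(X >= k), X ~ Hypergeom(M=m, n=|set|, N=|list|)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(members),
                "list_size": n,
                "universe_size": m,
                "p_value": min(p, 1.0),
                "members": ",".join(sorted(members & query)),
            }
        )
    out = pd.DataFrame(rows)
    out["overlap_fraction"] = out["overlap"] / out["set_size"].replace(0, pd.NA)
    out = out.sort_values(
        ["p_value", "overlap_fraction"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    if bh and len(out):
        from statsmodels.stats.multitest import multipletests

        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def top_pathways(results: pd.DataFrame, k: int = 3, alpha: float = 0.05) -> pd.DataFrame:
    """Top-k significant sets (p < alpha), report-style: name + overlap.

    Returns fewer than k rows when fewer sets are significant; no padding.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if results.empty:
        return results.copy()
    sig = results[results["p_value"] < alpha]
    return sig.head(k)[["set_name", "overlap", "set_size", "p_value"]].reset_index(drop=True)
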