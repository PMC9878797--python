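"""Hypergeometric over-representation analysis against GMT gene sets.

Database-agnostic stand-in for web GO-enrichment tools: each user-supplied
gene set is intersected with the testable universe (by default the genes
that entered the expression analysis) and scored with the upper-tail
hypergeometric probability; BH correction runs across the tested sets.
"""

from __future__ import annotations

import pandas as pd

from .formats_io import GeneSetCollection
from .stats_core import bh_adjust, hypergeom_tail

__all__ = ["run_ora"]


def run_ora(
    gene_list,
    collection: GeneSetCollection,
    universe,
    fdr: float = 0.05,
    min_set: int = 2,
    max_set: int = 2000,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each set of ``collection``.

    Parameters
    ----------
    gene_list : genes of interest; must be a subset of ``universe``.
    universe : all genes that could have been selected.
    min_set, max_set : size bounds applied AFTER intersecting each set
        with the universe; sets outside the bounds are not tested.

    Returns a DataFrame sorted by (q_value, p_value, set_name) with one
    row per tested set and a ``significant`` flag at ``q < fdr``.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not universe:
        raise ValueError("empty universe")
    if not genes:
        raise ValueError("empty gene list")
    stray = sorted(genes - universe)
    if stray:
        raise ValueError(f"gene list members outside the universe: {stray[:20]}")

    rows = []
    for name, members in collection.sets.items():
        in_universe = sorted(set(members) & universe)
        if not (min_set <= len(in_universe) <= max_set):
            continue
        overlap = sorted(set(in_universe) & genes)
        p = hypergeom_tail(len(overlap), len(in_universe), len(genes), len(universe))
        rows.append(
            {
                "set_name": name,
                "overlap_count": len(overlap),
                "set_size": len(in_universe),
                "list_size": len(genes),
                "universe_size": len(universe),
                "p_value": p,
                "overlap_members": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name", "overlap_count", "set_size", "list_size",
                "universe_size", "p_value", "q_value", "significant",
                "overlap_members",
            ]
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < fdr
    out = out.sort_values(["q_value", "p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return out[
        [
            "set_name", "overlap_count", "set_size", "list_size", "universe_size",
            "p_value", "q_value", "significant", "overlap_members",
        ]
    ]
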