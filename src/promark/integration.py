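"""Join consensus DEGs with differential promoter trimethylation.

Each shared DEG is classified by combining its expression direction with
the direction of its most significant differentially trimethylated
promoter peak:

* ``hyper_up``   — upregulated and promoter H3K4me3 gained in UL,
* ``hypo_down``  — downregulated and promoter H3K4me3 lost in UL,
* ``discordant`` — expression and mark change in opposite directions,
* ``no_differential_mark`` — no owned promoter peak passes the FDR cut
  (or no promoter peak at all).

Gene-level significance is the minimum q over owned promoter peaks; q is
computed once at peak level (no second gene-level correction).  Ties in
best-peak q break by smaller p, then lexicographic peak id, making the
classification deterministic and order-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus_de import DEGSet
from .promoter_chip import EnrichmentMatrix, GlobalComparison, global_h3k4me3_comparison

__all__ = [
    "VennSummary",
    "classify_genes",
    "group_h3k4_status_by_direction",
]

CLASSES = ("hyper_up", "hypo_down", "discordant", "no_differential_mark")


@dataclass(frozen=True)
class VennSummary:
    """Nested gene counts: shared DEGs ⊇ marked ⊇ differentially marked."""

    n_deg_shared: int
    n_with_promoter_mark: int
    n_differential: int
    n_hyper_up: int
    n_hypo_down: int
    n_discordant: int

    def __post_init__(self) -> None:
        if self.n_differential != self.n_hyper_up + self.n_hypo_down + self.n_discordant:
            raise ValueError("Venn identity violated: differential != hyper_up + hypo_down + discordant")
        if not (self.n_differential <= self.n_with_promoter_mark <= self.n_deg_shared):
            raise ValueError("Venn identity violated: differential <= marked <= shared DEGs")

    def to_dict(self) -> dict:
        return {
            "n_deg_shared": self.n_deg_shared,
            "n_with_promoter_mark": self.n_with_promoter_mark,
            "n_differential": self.n_differential,
            "n_hyper_up": self.n_hyper_up,
            "n_hypo_down": self.n_hypo_down,
            "n_discordant": self.n_discordant,
        }


def classify_genes(
    degs: DEGSet,
    assignments: pd.DataFrame,
    diff_peaks: pd.DataFrame,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, VennSummary]:
    """Classify each shared DEG by its promoter-mark change.

    Parameters
    ----------
    degs : shared (cohort-intersected) DEG set giving expression direction.
    assignments : peak-to-gene table from
        :func:`promark.promoter_chip.assign_peaks_to_promoters`.
    diff_peaks : differential trimethylation table from
        :func:`promark.promoter_chip.differential_peak_enrichment`.
    fdr : gene is "differential" iff its best owned peak has q < fdr.

    Returns (classification table, VennSummary); the summary's nesting
    identities are checked on construction, not assumed.
    """
    deg_dir = {g: "up" for g in degs.up}
    deg_dir.update({g: "down" for g in degs.down})

    owned = assignments.dropna(subset=["gene_id"])
    owned = owned[owned["gene_id"].isin(deg_dir)]
    merged = owned.merge(diff_peaks, on="peak_id", how="inner")

    tested_peak_owners = set(owned["peak_id"])
    orphans = sorted(set(diff_peaks["peak_id"]) - tested_peak_owners)
    if orphans:
        warnings.warn(
            f"{len(orphans)} differential peak(s) owned by no candidate DEG were ignored"
        )

    rows = []
    genes_with_mark = set(owned["gene_id"])
    by_gene = dict(tuple(merged.groupby("gene_id"))) if len(merged) else {}
    for gene in sorted(deg_dir):
        expr = deg_dir[gene]
        sub = by_gene.get(gene)
        if sub is None or len(sub) == 0:
            rows.append(
                {
                    "gene_id": gene,
                    "expression": expr,
                    "has_promoter_mark": gene in genes_with_mark,
                    "trimethylation": "none",
                    "class": "no_differential_mark",
                    "best_peak_id": None,
                    "best_peak_q": np.nan,
                }
            )
            continue
        best = sub.sort_values(["q_value", "p_value", "peak_id"]).iloc[0]
        if best["q_value"] < fdr:
            tri = best["direction"]
            if (expr == "up" and tri == "hyper"):
                cls = "hyper_up"
            elif (expr == "down" and tri == "hypo"):
                cls = "hypo_down"
            else:
                cls = "discordant"
        else:
            tri, cls = "none", "no_differential_mark"
        rows.append(
            {
                "gene_id": gene,
                "expression": expr,
                "has_promoter_mark": True,
                "trimethylation": tri,
                "class": cls,
                "best_peak_id": best["peak_id"],
                "best_peak_q": float(best["q_value"]),
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "expression", "has_promoter_mark", "trimethylation",
            "class", "best_peak_id", "best_peak_q",
        ],
    )
    n_classes = table["class"].value_counts()
    summary = VennSummary(
        n_deg_shared=len(deg_dir),
        n_with_promoter_mark=int(table["has_promoter_mark"].sum()),
        n_differential=int(
            n_classes.get("hyper_up", 0) + n_classes.get("hypo_down", 0) + n_classes.get("discordant", 0)
        ),
        n_hyper_up=int(n_classes.get("hyper_up", 0)),
        n_hypo_down=int(n_classes.get("hypo_down", 0)),
        n_discordant=int(n_classes.get("discordant", 0)),
    )
    return table, summary


def group_h3k4_status_by_direction(
    matrix: EnrichmentMatrix,
    assignments: pd.DataFrame,
    degs: DEGSet,
    sheet: pd.DataFrame,
) -> dict[str, GlobalComparison | None]:
    """UL-vs-MM enrichment comparison stratified by expression direction.

    Pools the standardized promoter-peak values of upregulated genes and
    of downregulated genes separately, testing each stratum with the
    rank-sum test.  An empty stratum yields None rather than an error.
    """
    owned = assignments.dropna(subset=["gene_id"])
    results: dict[str, GlobalComparison | None] = {}
    for label, genes in (("up", degs.up), ("down", degs.down)):
        peak_ids = sorted(set(owned.loc[owned["gene_id"].isin(genes), "peak_id"]))
        peak_ids = [p for p in peak_ids if p in matrix.values.index]
        if not peak_ids:
            results[label] = None
            continue
        results[label] = global_h3k4me3_comparison(matrix.subset_peaks(peak_ids), sheet)
    return results
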