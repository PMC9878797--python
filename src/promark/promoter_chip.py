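"""Promoter H3K4me3 quantification and differential trimethylation.

Peaks are anchored at their summit (midpoint fallback) and assigned to a
gene when the anchor falls within the closed promoter window TSS +/- 2 kb.
Per-sample fold-enrichment values over a master peak list are standardized
as (value - median) / sd, a missing peak contributing raw 0 beforehand.

The global tumor-vs-normal comparison pools all standardized peak values
per tissue into a Wilcoxon rank-sum test.  Because per-sample median
centering forces every column's median to zero (hence the pooled medians
of both tissues to ~zero), the reported direction is the difference in
mean standardized enrichment (equivalently, in mean rank), with medians
and quartiles reported alongside for the boxplot-style summary.

Differential trimethylation of individual promoter peaks uses the
empirical-Bayes moderated linear model with tissue effect and, by default,
patient blocks (the ChIP cohort is patient-matched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import GeneAnnotation, PeakRecord
from .stats_core import (
    TestResult,
    fit_moderated_linear_model,
    standardize_sample,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

__all__ = [
    "PromoterWindow",
    "compute_tss",
    "promoter_window",
    "assign_peaks_to_promoters",
    "EnrichmentMatrix",
    "build_enrichment_matrix",
    "GlobalComparison",
    "global_h3k4me3_comparison",
    "differential_peak_enrichment",
    "peak_key",
]

DEFAULT_FLANK = 2000


@dataclass(frozen=True)
class PromoterWindow:
    """Closed promoter interval [tss - flank, tss + flank], clipped at 0."""

    gene_id: str
    chrom: str
    window_start: int
    window_end: int
    tss: int
    flank: int = DEFAULT_FLANK


def compute_tss(gene: GeneAnnotation) -> int:
    """Transcription start site: interval start on +, last base on -."""
    return gene.start if gene.strand == "+" else gene.end - 1


def promoter_window(gene: GeneAnnotation, flank: int = DEFAULT_FLANK) -> PromoterWindow:
    tss = compute_tss(gene)
    return PromoterWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        window_start=max(0, tss - flank),
        window_end=tss + flank,
        tss=tss,
        flank=flank,
    )


def peak_key(peak: PeakRecord) -> str:
    """Stable identifier for a master-list peak: chrom:start-end."""
    return f"{peak.chrom}:{peak.start}-{peak.end}"


def _anchor_position(peak: PeakRecord, anchor: str) -> int:
    if anchor == "summit":
        return peak.summit
    if anchor == "midpoint":
        return peak.midpoint
    raise ValueError(f"unknown anchor {anchor!r}")


def assign_peaks_to_promoters(
    peaks: list[PeakRecord],
    genes: list[GeneAnnotation],
    flank: int = DEFAULT_FLANK,
    anchor: str = "summit",
) -> pd.DataFrame:
    """Assign peaks to promoter windows (TSS +/- flank, closed interval).

    With ``anchor='summit'`` (default) or ``'midpoint'`` a peak belongs to
    a gene when the anchor base lies inside the window; with
    ``'any-overlap'`` any overlap of the peak interval with the window
    suffices.  A peak may own several genes and vice versa; unassigned
    peaks appear once with a null gene_id.

    Returns a DataFrame with columns peak_id (the stable chrom:start-end
    key used by the enrichment matrix), peak_name, gene_id,
    distance_to_tss (signed, negative = upstream in gene orientation; NaN
    when a peak that merely overlaps has its anchor outside the window).
    """
    windows: dict[str, list[PromoterWindow]] = {}
    for g in genes:
        windows.setdefault(g.chrom, []).append(promoter_window(g, flank))
    for chrom_windows in windows.values():
        chrom_windows.sort(key=lambda w: w.window_start)

    rows = []
    for peak in peaks:
        pid = peak_key(peak)
        hits = []
        for w in windows.get(peak.chrom, []):
            if anchor == "any-overlap":
                inside = peak.start <= w.window_end and peak.end - 1 >= w.window_start
                pos = peak.summit
            else:
                pos = _anchor_position(peak, anchor)
                inside = w.window_start <= pos <= w.window_end
            if inside:
                sign = 1 if _strand_of(genes, w.gene_id) == "+" else -1
                dist = (pos - w.tss) * sign
                if abs(dist) > w.flank:
                    dist = float("nan")
                hits.append((w.gene_id, dist))
        if hits:
            for gene_id, dist in hits:
                rows.append(
                    {"peak_id": pid, "peak_name": peak.name, "gene_id": gene_id,
                     "distance_to_tss": dist}
                )
        else:
            rows.append(
                {"peak_id": pid, "peak_name": peak.name, "gene_id": None,
                 "distance_to_tss": np.nan}
            )
    return pd.DataFrame(rows, columns=["peak_id", "peak_name", "gene_id", "distance_to_tss"])


def _strand_of(genes: list[GeneAnnotation], gene_id: str) -> str:
    # small helper kept O(1) via cached map on first use
    cache = getattr(_strand_of, "_cache", None)
    if cache is None or cache[0] is not genes:
        cache = (genes, {g.gene_id: g.strand for g in genes})
        _strand_of._cache = cache
    return cache[1][gene_id]


@dataclass
class EnrichmentMatrix:
    """Peak x sample fold-enrichment values over a master peak list."""

    values: pd.DataFrame               # peak_id x sample_id
    provenance: str                    # "raw" | "standardized"
    master_peaks: list[PeakRecord] = field(default_factory=list)
    excluded_samples: list[str] = field(default_factory=list)

    def subset_peaks(self, peak_ids) -> "EnrichmentMatrix":
        keep = [p for p in peak_ids if p in self.values.index]
        return EnrichmentMatrix(
            values=self.values.loc[keep],
            provenance=self.provenance,
            master_peaks=[p for p in self.master_peaks if peak_key(p) in set(keep)],
            excluded_samples=list(self.excluded_samples),
        )


def build_enrichment_matrix(
    sample_peaks: dict[str, list[PeakRecord]],
    master_peaks: list[PeakRecord] | None = None,
    standardize: bool = True,
) -> EnrichmentMatrix:
    """Assemble the fold-enrichment matrix across samples.

    Peaks are matched across samples by identical (chrom, start, end).
    The master list defaults to the union over samples.  A sample missing
    a master peak contributes raw value 0 for it, imposed BEFORE
    standardization.  Samples with no detected peaks (or zero variance)
    are excluded with a warning.
    """
    if master_peaks is None:
        seen: dict[str, PeakRecord] = {}
        for plist in sample_peaks.values():
            for p in plist:
                seen.setdefault(peak_key(p), p)
        master_peaks = sorted(seen.values(), key=lambda p: (p.chrom, p.start, p.end))
    keys = [peak_key(p) for p in master_peaks]
    key_pos = {k: i for i, k in enumerate(keys)}

    excluded: list[str] = []
    columns: dict[str, np.ndarray] = {}
    for sample, plist in sample_peaks.items():
        if len(plist) == 0:
            warnings.warn(f"sample {sample!r} has no detected peaks; excluded")
            excluded.append(sample)
            continue
        col = np.zeros(len(keys), dtype=float)
        for p in plist:
            i = key_pos.get(peak_key(p))
            if i is not None:
                col[i] = p.signal_value
        columns[sample] = col

    raw = pd.DataFrame(columns, index=pd.Index(keys, name="peak_id"))
    if not standardize:
        return EnrichmentMatrix(raw, "raw", master_peaks, excluded)

    std_cols = {}
    for sample in raw.columns:
        try:
            std_cols[sample] = standardize_sample(raw[sample].to_numpy())
        except ValueError as exc:
            warnings.warn(f"sample {sample!r} excluded from standardization: {exc}")
            excluded.append(sample)
    std = pd.DataFrame(std_cols, index=raw.index)
    return EnrichmentMatrix(std, "standardized", master_peaks, excluded)


@dataclass
class GlobalComparison:
    """Pooled tumor-vs-normal comparison of standardized enrichment."""

    test: TestResult
    direction: float                   # mean(UL) - mean(MM), standardized units
    summary: pd.DataFrame              # per-tissue median and quartiles


def _tissue_samples(matrix: EnrichmentMatrix, sheet: pd.DataFrame, tissue: str) -> list[str]:
    meta = sheet.set_index("sample_id")
    return [s for s in matrix.values.columns if s in meta.index and meta.loc[s, "tissue"] == tissue]


def global_h3k4me3_comparison(
    matrix: EnrichmentMatrix,
    sheet: pd.DataFrame,
    paired: bool = False,
) -> GlobalComparison:
    """Test for a global trimethylation shift between UL and MM.

    Pools every standardized peak value per tissue and applies the
    Wilcoxon rank-sum test (alternative: a signed-rank test on per-peak
    within-patient differences with ``paired=True``).
    """
    ul_samples = _tissue_samples(matrix, sheet, "UL")
    mm_samples = _tissue_samples(matrix, sheet, "MM")
    if not ul_samples or not mm_samples:
        raise ValueError("both tissues must be present in the enrichment matrix")
    ul_vals = matrix.values[ul_samples].to_numpy().ravel()
    mm_vals = matrix.values[mm_samples].to_numpy().ravel()

    if paired:
        meta = sheet.set_index("sample_id")
        by_patient_ul = {meta.loc[s, "patient_id"]: s for s in ul_samples}
        by_patient_mm = {meta.loc[s, "patient_id"]: s for s in mm_samples}
        common = sorted(set(by_patient_ul) & set(by_patient_mm))
        if not common:
            raise ValueError("paired comparison requires matched patients")
        diffs = np.concatenate(
            [
                matrix.values[by_patient_ul[p]].to_numpy()
                - matrix.values[by_patient_mm[p]].to_numpy()
                for p in common
            ]
        )
        test = wilcoxon_signed_rank(diffs)
    else:
        test = wilcoxon_rank_sum(ul_vals, mm_vals)

    summary = pd.DataFrame(
        {
            "tissue": ["UL", "MM"],
            "median": [np.median(ul_vals), np.median(mm_vals)],
            "q1": [np.percentile(ul_vals, 25), np.percentile(mm_vals, 25)],
            "q3": [np.percentile(ul_vals, 75), np.percentile(mm_vals, 75)],
            "mean": [ul_vals.mean(), mm_vals.mean()],
        }
    )
    direction = float(ul_vals.mean() - mm_vals.mean())
    return GlobalComparison(test=test, direction=direction, summary=summary)


def differential_peak_enrichment(
    matrix: EnrichmentMatrix,
    sheet: pd.DataFrame,
    paired: bool = True,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Moderated-t differential trimethylation per peak (UL vs MM).

    ``matrix`` should already be restricted to the promoter peaks of the
    candidate genes; BH correction runs across exactly the tested peaks.
    Returns a DataFrame: peak_id, delta (standardized UL - MM), t_moderated,
    p_value, q_value, direction (hyper/hypo), significant (q < fdr).
    """
    samples = list(matrix.values.columns)
    meta = sheet.set_index("sample_id").loc[samples]
    tissue = (meta["tissue"] == "UL").to_numpy(dtype=float)
    if tissue.sum() < 2 or (1 - tissue).sum() < 2:
        raise ValueError("need >= 2 samples per tissue")
    if paired:
        counts = meta.groupby("patient_id")["tissue"].nunique()
        incomplete = sorted(counts[counts < 2].index)
        if incomplete:
            raise ValueError(f"paired analysis but incomplete pairs for patients: {incomplete}")
        blocks = pd.get_dummies(meta["patient_id"], drop_first=True).to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(samples)), tissue, blocks])
        contrast = np.zeros(design.shape[1])
        contrast[1] = 1.0
    else:
        design = np.column_stack([np.ones(len(samples)), tissue])
        contrast = np.array([0.0, 1.0])

    fit = fit_moderated_linear_model(
        matrix.values.to_numpy(), design, contrast, feature_ids=matrix.values.index
    )
    out = pd.DataFrame(
        {
            "peak_id": fit["feature_id"],
            "delta": fit["effect"],
            "t_moderated": fit["t_moderated"],
            "p_value": fit["p_value"],
            "q_value": fit["q_value"],
        }
    )
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    out["significant"] = out["q_value"] < fdr
    return out
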