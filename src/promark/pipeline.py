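"""End-to-end orchestration: QC -> DE per cohort -> intersection ->
promoter ChIP -> classification -> ORA (-> qPCR), with a machine-readable
run manifest.

`run_bundle` drives the whole analysis on in-memory objects (this is what
the tests and the acceptance script exercise); `run_pipeline` is the
file-based wrapper that reads a :class:`RunConfig`, executes the stages in
order, and writes every stage's table plus a JSON Venn summary, QC report
and manifest into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus_de import (
    DEGSet,
    consensus_degs,
    estimate_dispersion,
    intersect_datasets,
    logcpm_moderated_test,
    nb_exact_test,
    nb_wald_test,
    size_factors_median_ratio,
)
from .formats_io import (
    GeneSetCollection,
    read_count_matrix,
    read_ct_table,
    read_gene_annotation,
    read_gmt,
    read_narrowpeak,
    read_sample_sheet,
    write_results_table,
)
from .integration import VennSummary, classify_genes, group_h3k4_status_by_direction
from .promoter_chip import (
    EnrichmentMatrix,
    assign_peaks_to_promoters,
    build_enrichment_matrix,
    differential_peak_enrichment,
    global_h3k4me3_comparison,
)
from .qpcr import delta_delta_ct
from .stats_core import pca

logger = logging.getLogger("promark")

__all__ = ["RunConfig", "QCReport", "qc_flag_samples", "run_bundle", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one pipeline run."""

    annotation: str = ""
    counts: dict[str, str] = field(default_factory=dict)       # cohort -> TSV
    sample_sheets: dict[str, str] = field(default_factory=dict)
    chip_sample_sheet: str = ""
    peak_dir: str = ""                                         # narrowPeak per sample
    gene_sets: str | None = None                               # GMT, optional
    ct_table: str | None = None                                # qPCR, optional
    housekeeping: str = "GAPDH"
    out_dir: str = "promark_out"
    # thresholds
    deg_fdr: float = 0.01
    deg_min_abs_log2fc: float = 1.0
    peak_fdr: float = 0.05
    ora_fdr: float = 0.05
    # flags
    paired_de: bool = False
    paired_chip: bool = True
    consensus_rule: str = "intersection"
    anchor: str = "summit"
    promoter_flank: int = 2000
    apply_qc: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deg_fdr", "peak_fdr", "ora_fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class QCReport:
    """Per-sample QC metrics and exclusion flags (report-only by default)."""

    metrics: pd.DataFrame        # sample_id, library_size, pca1, pca2, ...
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (sample, reason)

    @property
    def excluded_samples(self) -> list[str]:
        return [s for s, _ in self.excluded]


def qc_flag_samples(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    depth_min_fraction: float = 0.25,
    pca_sd: float = 4.0,
    paired: bool = False,
) -> QCReport:
    """Flag low-depth and PCA-outlier samples.

    A sample is flagged ``low_depth`` when its library size falls below
    ``depth_min_fraction`` of the median library size, and ``pca_outlier``
    when its standardized (PC1, PC2) score lies more than ``pca_sd``
    standard deviations from the centroid.  In paired mode the matched
    sample of a flagged one is excluded too.  Report-only: callers decide
    whether to drop.
    """
    if matrix.shape[1] < 4:
        raise ValueError("QC needs at least 4 samples")
    lib = matrix.sum(axis=0)
    med = float(lib.median())
    flagged: dict[str, str] = {}
    for s, size in lib.items():
        if size < depth_min_fraction * med:
            flagged.setdefault(s, "low_depth")

    logm = np.log2(matrix.to_numpy(dtype=float) + 0.5)
    scores, frac = pca(logm, n_components=2)
    k = scores.shape[1]
    dist2 = np.zeros(scores.shape[0])
    for j in range(min(2, k)):
        sd_j = scores[:, j].std(ddof=1)
        if sd_j > 0:
            dist2 += ((scores[:, j] - scores[:, j].mean()) / sd_j) ** 2
    dist = np.sqrt(dist2)
    for s, d in zip(matrix.columns, dist):
        if d > pca_sd:
            flagged.setdefault(s, "pca_outlier")

    if paired and flagged:
        meta = sheet.set_index("sample_id")
        for s in list(flagged):
            if s not in meta.index:
                continue
            pat, ds = meta.loc[s, "patient_id"], meta.loc[s, "dataset_id"]
            partners = meta[(meta.patient_id == pat) & (meta.dataset_id == ds)].index
            for partner in partners:
                if partner != s:
                    flagged.setdefault(partner, f"partner_of:{s}")

    metrics = pd.DataFrame(
        {
            "sample_id": matrix.columns,
            "library_size": lib.to_numpy(),
            "pc1": scores[:, 0] if k >= 1 else 0.0,
            "pc2": scores[:, 1] if k >= 2 else 0.0,
            "pca_distance": dist,
            "flag": [flagged.get(s, "") for s in matrix.columns],
        }
    )
    return QCReport(metrics=metrics, excluded=sorted(flagged.items()))


# ---------------------------------------------------------------------------
# in-memory end-to-end run
# ---------------------------------------------------------------------------


def run_de_cohort(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    dataset_id: str,
    fdr: float = 0.01,
    min_abs_log2fc: float = 1.0,
    rule: str = "intersection",
    paired: bool = False,
) -> tuple[DEGSet, pd.DataFrame]:
    """Three-method consensus DE for one cohort.

    Returns the DEG set and a merged per-gene table with each method's
    log2FC and q-value.
    """
    sf = size_factors_median_ratio(counts)
    _, disp = estimate_dispersion(counts, sheet, sf)
    results = [
        nb_exact_test(counts, sheet, sf, disp),
        nb_wald_test(counts, sheet, sf, disp),
        logcpm_moderated_test(counts, sheet, sf, paired=paired),
    ]
    degs = consensus_degs(results, dataset_id, fdr=fdr, min_abs_log2fc=min_abs_log2fc, rule=rule)
    merged = results[0][["gene_id"]].copy()
    for r in results:
        tag = r["method"].iloc[0]
        merged[f"log2FC_{tag}"] = r["log2FC"].to_numpy()
        merged[f"q_{tag}"] = r["q_value"].to_numpy()
    verdict = np.where(
        merged["gene_id"].isin(degs.up), "up",
        np.where(merged["gene_id"].isin(degs.down), "down", "ns"),
    )
    merged["consensus"] = verdict
    return degs, merged


def run_bundle(
    genes,
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    chip_sample_peaks: dict,
    chip_sheet: pd.DataFrame,
    master_peaks=None,
    gene_sets: GeneSetCollection | None = None,
    deg_fdr: float = 0.01,
    deg_min_abs_log2fc: float = 1.0,
    peak_fdr: float = 0.05,
    ora_fdr: float = 0.05,
    consensus_rule: str = "intersection",
    paired_de: bool = False,
    paired_chip: bool = True,
    anchor: str = "summit",
    promoter_flank: int = 2000,
) -> dict:
    """Execute every analysis stage on in-memory inputs.

    Returns a dict with the per-cohort DE tables and DEG sets, the shared
    DEG set, enrichment matrix, global comparison, peak assignments,
    differential peaks, gene classification, Venn summary, direction
    strata and (when gene sets are given) the ORA table.
    """
    out: dict = {}
    deg_sets = {}
    for cid, (counts, sheet) in cohorts.items():
        degs, table = run_de_cohort(
            counts, sheet, cid, fdr=deg_fdr, min_abs_log2fc=deg_min_abs_log2fc,
            rule=consensus_rule, paired=paired_de,
        )
        deg_sets[cid] = degs
        out[f"de_table_{cid}"] = table
    out["deg_sets"] = deg_sets
    ids = sorted(deg_sets)
    if len(ids) != 2:
        raise ValueError("expected exactly two cohorts")
    shared = intersect_datasets(deg_sets[ids[0]], deg_sets[ids[1]])
    out["shared_degs"] = shared

    matrix = build_enrichment_matrix(chip_sample_peaks, master_peaks=master_peaks)
    out["enrichment_matrix"] = matrix
    out["global_comparison"] = global_h3k4me3_comparison(matrix, chip_sheet)

    assignments = assign_peaks_to_promoters(
        matrix.master_peaks, genes, flank=promoter_flank, anchor=anchor
    )
    out["assignments"] = assignments

    deg_genes = shared.up | shared.down
    promoter_peak_ids = sorted(
        set(
            assignments.loc[
                assignments["gene_id"].isin(deg_genes), "peak_id"
            ].dropna()
        )
    )
    out["promoter_peak_ids"] = promoter_peak_ids
    if promoter_peak_ids:
        sub = matrix.subset_peaks(promoter_peak_ids)
        diff_peaks = differential_peak_enrichment(
            sub, chip_sheet, paired=paired_chip, fdr=peak_fdr
        )
    else:
        diff_peaks = pd.DataFrame(
            columns=["peak_id", "delta", "t_moderated", "p_value", "q_value", "direction", "significant"]
        )
    out["diff_peaks"] = diff_peaks

    classification, venn = classify_genes(shared, assignments, diff_peaks, fdr=peak_fdr)
    out["classification"] = classification
    out["venn"] = venn
    out["direction_strata"] = group_h3k4_status_by_direction(
        matrix, assignments, shared, chip_sheet
    )

    if gene_sets is not None and len(deg_genes):
        universe = set(cohorts[ids[0]][0].index)
        diff_genes = classification.loc[
            classification["class"].isin(["hyper_up", "hypo_down", "discordant"]), "gene_id"
        ]
        target = sorted(set(diff_genes) & universe) or sorted(deg_genes & universe)
        out["ora"] = run_ora_safe(target, gene_sets, universe, fdr=ora_fdr)
    return out


def run_ora_safe(gene_list, collection, universe, fdr=0.05):
    from .ora import run_ora

    if not gene_list:
        return None
    return run_ora(gene_list, collection, universe, fdr=fdr)


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline from files per ``config``; returns out_dir.

    Writes per-stage TSVs, a Venn summary JSON, QC reports, a log and a
    manifest (config + package version + seed) sufficient to reproduce
    the run.  Any stage failure aborts with a stage-named message;
    partial outputs are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    stage = "load-inputs"
    try:
        genes = read_gene_annotation(config.annotation)
        cohorts = {}
        for cid, cpath in config.counts.items():
            counts = read_count_matrix(cpath)
            sheet = read_sample_sheet(config.sample_sheets[cid])
            cohorts[cid] = (counts, sheet)
        chip_sheet = read_sample_sheet(config.chip_sample_sheet)
        peak_dir = Path(config.peak_dir)
        chip_sample_peaks = {}
        for sid in chip_sheet["sample_id"]:
            path = peak_dir / f"{sid}.narrowPeak"
            if not path.exists():
                raise FileNotFoundError(f"no peak file for sample {sid}: {path}")
            chip_sample_peaks[sid] = read_narrowpeak(path)
        gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None

        stage = "qc"
        qc_reports = {}
        for cid, (counts, sheet) in cohorts.items():
            rep = qc_flag_samples(counts, sheet, paired=True)
            qc_reports[cid] = rep
            write_results_table(rep.metrics, out_dir / f"qc_{cid}.tsv")
            if config.apply_qc and rep.excluded_samples:
                keep = [s for s in counts.columns if s not in rep.excluded_samples]
                cohorts[cid] = (
                    counts[keep],
                    sheet[sheet.sample_id.isin(keep)].reset_index(drop=True),
                )
                logger.info("%s: excluded %s", cid, rep.excluded_samples)

        stage = "analysis"
        res = run_bundle(
            genes,
            cohorts,
            chip_sample_peaks,
            chip_sheet,
            gene_sets=gene_sets,
            deg_fdr=config.deg_fdr,
            deg_min_abs_log2fc=config.deg_min_abs_log2fc,
            peak_fdr=config.peak_fdr,
            ora_fdr=config.ora_fdr,
            consensus_rule=config.consensus_rule,
            paired_de=config.paired_de,
            paired_chip=config.paired_chip,
            anchor=config.anchor,
            promoter_flank=config.promoter_flank,
        )

        stage = "write-outputs"
        for cid in cohorts:
            write_results_table(res[f"de_table_{cid}"], out_dir / f"de_{cid}.tsv")
        shared = res["shared_degs"]
        write_results_table(
            pd.DataFrame(
                {
                    "gene_id": sorted(shared.up) + sorted(shared.down),
                    "direction": ["up"] * len(shared.up) + ["down"] * len(shared.down),
                }
            ),
            out_dir / "shared_degs.tsv",
        )
        write_results_table(res["assignments"], out_dir / "peak_assignments.tsv")
        write_results_table(res["diff_peaks"], out_dir / "differential_peaks.tsv")
        write_results_table(res["classification"], out_dir / "gene_classification.tsv")
        with open(out_dir / "venn_summary.json", "w") as fh:
            json.dump(res["venn"].to_dict(), fh, indent=2)
        gc = res["global_comparison"]
        with open(out_dir / "global_comparison.json", "w") as fh:
            json.dump(
                {
                    "statistic": gc.test.statistic,
                    "p_value": gc.test.p_value,
                    "method": gc.test.method,
                    "direction_mean_UL_minus_MM": gc.direction,
                    "summary": gc.summary.to_dict(orient="records"),
                },
                fh,
                indent=2,
            )
        if res.get("ora") is not None:
            write_results_table(res["ora"], out_dir / "ora.tsv")

        stage = "qpcr"
        if config.ct_table:
            ct = read_ct_table(config.ct_table)
            targets = sorted(set(ct["gene"]) - {config.housekeeping})
            rows = []
            for gene in targets:
                r = delta_delta_ct(ct, gene, config.housekeeping)
                rows.append(dataclasses.asdict(r))
            write_results_table(pd.DataFrame(rows), out_dir / "qpcr_fold_changes.tsv")

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "promark_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir
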