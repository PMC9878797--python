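"""Synthetic paired tumor/normal multi-omic cohorts with planted truth.

Emulates the structure of the real study inputs without any download: two
independent RNA-seq cohorts of patient-matched UL/MM pairs with
negative-binomial counts, plus one patient-matched ChIP cohort whose
promoter peaks carry log-normal fold-enrichment signals.  Ground truth
(which genes are differentially expressed, which promoters gain or lose
the mark) is recorded so every pipeline stage can be scored.

Model sketch
------------
* counts ~ NB(mu_g * e^(patient effect) * size_factor * 2^(+-lfc/2), alpha)
  with the half-log2FC split between tissues and a per-(gene, patient)
  log-normal random effect (sd 0.1) inducing the pairing structure.
* promoter peaks: summit uniform in TSS +- 1 kb, 400 bp wide; log2
  fold-enrichment = base + patient effect + tissue shifts + noise.
* "SD units" for mark shifts refer to the cross-peak standard deviation
  of log2 fold-enrichment (``peak_log2_sd``).
* the global UL trimethylation deficit compresses the log2 dynamic range
  of UL signals toward the cross-peak mean: log2 signal becomes
  mean + gamma * (base - mean) with gamma = 1 + coupling * shift, so the
  strongest promoter domains lose the most mark.  The mechanism matters:
  per-sample median/sd standardization cancels any uniform additive or
  multiplicative shift exactly, whereas range compression survives it
  with the correct (negative) sign in the pooled standardized values.
* a concordant subset of shared DE genes additionally gains (up genes) or
  loses (down genes) promoter signal by ``mark_shift_sd`` SD units.

Everything derives from one integer seed; identical configs produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formats_io import (
    GeneAnnotation,
    PeakRecord,
    write_count_matrix,
    write_gene_annotation_bed,
    write_narrowpeak,
    write_sample_sheet,
)
from .promoter_chip import compute_tss, peak_key

__all__ = ["SimConfig", "SyntheticBundle", "simulate_dataset", "simulate_null"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated two-cohort study (the planted world)."""

    n_genes: int = 2000
    n_pairs: int = 8                       # UL/MM pairs per cohort
    n_chroms: int = 2
    gene_spacing: int = 50_000
    gene_length: int = 10_000
    # RNA-seq model
    nb_mean_log_mean: float = 4.0          # natural-log mean of gene means
    nb_mean_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    library_size_log_sd: float = 0.3
    patient_effect_sd: float = 0.1         # per (gene, patient), natural log
    frac_de: float = 0.15
    de_log2fc: float = 2.0
    frac_de_shared: float = 1.0            # DE genes planted in both cohorts
    # ChIP model
    frac_genes_with_promoter_peak: float = 0.75
    frac_background_peaks: float = 0.2     # extra non-promoter peaks / n_genes
    peak_log2_mean: float = 3.0
    peak_log2_sd: float = 1.0              # defines the "SD unit" for shifts
    peak_noise_log2_sd: float = 0.35
    peak_patient_sd: float = 0.2
    global_ul_shift: float = 0.0           # SD units; negative = hypotrimethylation
    global_shift_coupling: float = 0.6     # dynamic-range loss per SD of shift
    frac_concordant: float = 0.6           # of shared DE genes
    mark_shift_sd: float = 1.0             # SD units for concordant genes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_de", "frac_de_shared", "frac_genes_with_promoter_peak",
            "frac_concordant", "frac_background_peaks",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_pairs < 3:
            raise ValueError("need at least 3 UL/MM pairs per cohort")
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticBundle:
    """In-memory synthetic study plus writers for the on-disk formats."""

    config: SimConfig
    genes: list[GeneAnnotation]
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]]   # id -> (counts, sheet)
    chip_sheet: pd.DataFrame
    chip_sample_peaks: dict[str, list[PeakRecord]]
    master_peaks: list[PeakRecord]
    truth: pd.DataFrame
    peak_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir) -> Path:
        """Emit the bundle in exactly the formats the readers accept."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_annotation_bed(self.genes, outdir / "genes.bed")
        for cid, (counts, sheet) in self.cohorts.items():
            write_count_matrix(counts, outdir / f"counts_{cid}.tsv")
            write_sample_sheet(sheet, outdir / f"samples_{cid}.tsv")
        write_sample_sheet(self.chip_sheet, outdir / "samples_chip.tsv")
        peak_dir = outdir / "peaks"
        peak_dir.mkdir(exist_ok=True)
        for sample, plist in self.chip_sample_peaks.items():
            write_narrowpeak(plist, peak_dir / f"{sample}.narrowPeak")
        write_narrowpeak(self.master_peaks, outdir / "master_peaks.narrowPeak")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if len(self.peak_truth):
            self.peak_truth.to_csv(outdir / "peak_truth.tsv", sep="\t", index=False)
        with open(outdir / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        return outdir


def _make_genes(cfg: SimConfig) -> list[GeneAnnotation]:
    genes = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    for i in range(cfg.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        slot = i % per_chrom
        start = 10_000 + slot * cfg.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i:05d}",
                chrom=chrom,
                start=start,
                end=start + cfg.gene_length,
                strand=strand,
            )
        )
    return genes


def _plant_truth(cfg: SimConfig, genes: list[GeneAnnotation], rng: np.random.Generator):
    n = cfg.n_genes
    gene_ids = np.array([g.gene_id for g in genes])
    n_de = int(round(cfg.frac_de * n))
    n_shared = int(round(cfg.frac_de_shared * n_de))
    order = rng.permutation(n)
    de_idx = order[:n_de]
    shared_idx = de_idx[:n_shared]
    a_only = de_idx[n_shared:][: (n_de - n_shared) // 2]
    b_only = de_idx[n_shared + len(a_only):]

    direction = np.full(n, "none", dtype=object)
    # alternate up/down within the DE block for an even split
    for j, gi in enumerate(de_idx):
        direction[gi] = "up" if j % 2 == 0 else "down"

    de_a = np.full(n, "none", dtype=object)
    de_b = np.full(n, "none", dtype=object)
    for gi in np.concatenate([shared_idx, a_only]).astype(int):
        de_a[gi] = direction[gi]
    for gi in np.concatenate([shared_idx, b_only]).astype(int):
        de_b[gi] = direction[gi]

    has_peak = rng.random(n) < cfg.frac_genes_with_promoter_peak
    n_conc = int(round(cfg.frac_concordant * n_shared))
    conc_idx = shared_idx[:n_conc]
    mark = np.full(n, "none", dtype=object)
    for gi in conc_idx:
        has_peak[gi] = True               # concordance requires a promoter peak
        mark[gi] = "hyper" if direction[gi] == "up" else "hypo"

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_de_cohortA": de_a,
            "true_de_cohortB": de_b,
            "true_mark_shift": mark,
            "has_promoter_peak": has_peak,
        }
    )


def _simulate_counts(
    cfg: SimConfig, truth: pd.DataFrame, cohort: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n, m = cfg.n_genes, cfg.n_pairs
    de = truth[f"true_de_{cohort}"].to_numpy()
    lfc = np.where(de == "up", cfg.de_log2fc, np.where(de == "down", -cfg.de_log2fc, 0.0))

    mu = rng.lognormal(cfg.nb_mean_log_mean, cfg.nb_mean_log_sd, size=n)
    pat_eff = rng.normal(0.0, cfg.patient_effect_sd, size=(n, m))
    lib = np.exp(rng.normal(0.0, cfg.library_size_log_sd, size=2 * m))

    patients = [f"{cohort[-1]}{i + 1:02d}" for i in range(m)]
    samples, tissues, pats = [], [], []
    cols = {}
    for j, pat in enumerate(patients):
        for tissue, sign in (("UL", +0.5), ("MM", -0.5)):
            s_idx = len(samples)
            mean = mu * np.exp(pat_eff[:, j]) * lib[s_idx] * 2.0 ** (sign * lfc)
            if cfg.nb_dispersion > 0:
                r = 1.0 / cfg.nb_dispersion
                k = rng.negative_binomial(r, r / (r + mean))
            else:
                k = rng.poisson(mean)
            sid = f"{tissue}_{pat}"
            cols[sid] = k.astype(np.int64)
            samples.append(sid)
            tissues.append(tissue)
            pats.append(pat)
    counts = pd.DataFrame(cols, index=pd.Index(truth["gene_id"], name="gene_id"))
    sheet = pd.DataFrame(
        {"sample_id": samples, "patient_id": pats, "tissue": tissues, "dataset_id": cohort}
    )
    return counts, sheet


def _simulate_chip(
    cfg: SimConfig, genes: list[GeneAnnotation], truth: pd.DataFrame, rng: np.random.Generator
):
    flank_summit = 1000
    width = 400
    peaks: list[PeakRecord] = []
    owner: list[str | None] = []
    gene_by_id = {g.gene_id: g for g in genes}

    for gid, has_peak in zip(truth["gene_id"], truth["has_promoter_peak"]):
        if not has_peak:
            continue
        g = gene_by_id[gid]
        tss = compute_tss(g)
        summit = int(rng.integers(tss - flank_summit, tss + flank_summit + 1))
        start = max(0, summit - width // 2)
        peaks.append(
            PeakRecord(
                chrom=g.chrom,
                start=start,
                end=start + width,
                name=f"peak_{gid}",
                signal_value=1.0,         # placeholder; per-sample values below
                summit_offset=summit - start,
            )
        )
        owner.append(gid)

    n_bg = int(round(cfg.frac_background_peaks * cfg.n_genes))
    bg_genes = rng.choice(len(genes), size=n_bg, replace=False)
    for i in sorted(bg_genes):
        g = genes[i]
        summit = g.start + 25_000 + int(rng.integers(-2000, 2001))
        start = summit - width // 2
        peaks.append(
            PeakRecord(
                chrom=g.chrom,
                start=start,
                end=start + width,
                name=f"bg_{g.gene_id}",
                signal_value=1.0,
                summit_offset=summit - start,
            )
        )
        owner.append(None)

    n_peaks = len(peaks)
    sd_unit = cfg.peak_log2_sd
    base = rng.normal(cfg.peak_log2_mean, cfg.peak_log2_sd, size=n_peaks)
    mark = truth.set_index("gene_id")["true_mark_shift"]
    mark_delta = np.zeros(n_peaks)
    for i, gid in enumerate(owner):
        if gid is not None and mark[gid] != "none":
            mark_delta[i] = cfg.mark_shift_sd * sd_unit * (1 if mark[gid] == "hyper" else -1)
    # global deficit: compress the UL dynamic range around the mean signal
    gamma = max(0.05, 1.0 + cfg.global_shift_coupling * cfg.global_ul_shift)
    global_delta = (gamma - 1.0) * (base - cfg.peak_log2_mean)

    patients = [f"B{i + 1:02d}" for i in range(cfg.n_pairs)]
    pat_eff = rng.normal(0.0, cfg.peak_patient_sd, size=(n_peaks, cfg.n_pairs))

    sample_peaks: dict[str, list[PeakRecord]] = {}
    samples, tissues, pats = [], [], []
    for j, pat in enumerate(patients):
        for tissue in ("UL", "MM"):
            shift = (mark_delta + global_delta) if tissue == "UL" else 0.0
            noise = rng.normal(0.0, cfg.peak_noise_log2_sd, size=n_peaks)
            log2v = base + pat_eff[:, j] + shift + noise
            values = np.power(2.0, log2v)
            sid = f"chip_{tissue}_{pat}"
            sample_peaks[sid] = [
                dataclasses.replace(p, signal_value=float(v)) for p, v in zip(peaks, values)
            ]
            samples.append(sid)
            tissues.append(tissue)
            pats.append(pat)
    chip_sheet = pd.DataFrame(
        {"sample_id": samples, "patient_id": pats, "tissue": tissues, "dataset_id": "chip"}
    )
    peak_truth = pd.DataFrame(
        {
            "peak_id": [peak_key(p) for p in peaks],
            "name": [p.name for p in peaks],
            "gene_id": [o if o is not None else "" for o in owner],
            "mark_shift": [
                mark[o] if o is not None else "none" for o in owner
            ],
        }
    )
    return chip_sheet, sample_peaks, peaks, peak_truth


def simulate_dataset(config: SimConfig) -> SyntheticBundle:
    """Generate the full two-cohort bundle described by ``config``."""
    rng = np.random.default_rng(config.seed)
    genes = _make_genes(config)
    truth = _plant_truth(config, genes, rng)
    counts_a, sheet_a = _simulate_counts(config, truth, "cohortA", rng)
    counts_b, sheet_b = _simulate_counts(config, truth, "cohortB", rng)
    chip_sheet, sample_peaks, master_peaks, peak_truth = _simulate_chip(
        config, genes, truth, rng
    )
    return SyntheticBundle(
        config=config,
        genes=genes,
        cohorts={"cohortA": (counts_a, sheet_a), "cohortB": (counts_b, sheet_b)},
        chip_sheet=chip_sheet,
        chip_sample_peaks=sample_peaks,
        master_peaks=master_peaks,
        truth=truth,
        peak_truth=peak_truth,
    )


def simulate_null(config: SimConfig) -> SyntheticBundle:
    """Same cohort structure with every planted effect forced to zero."""
    null_cfg = dataclasses.replace(
        config,
        frac_de=0.0,
        de_log2fc=0.0,
        frac_concordant=0.0,
        mark_shift_sd=0.0,
        global_ul_shift=0.0,
    )
    return simulate_dataset(null_cfg)
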