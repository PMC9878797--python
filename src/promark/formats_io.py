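"""Readers and writers for every external format the pipeline touches.

All internal coordinates are 0-based, half-open; conversions to and from
1-based closed conventions (GTF) happen only at the parse/write boundary.
Gene identifiers are opaque strings — no symbol/accession translation is
attempted, so all inputs must share one identifier namespace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "PeakRecord",
    "read_gene_annotation",
    "read_narrowpeak",
    "write_gene_annotation_bed",
    "write_narrowpeak",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_ct_table",
    "write_results_table",
    "read_results_table",
]

TISSUES = ("UL", "MM")


@dataclass(frozen=True)
class GeneAnnotation:
    """A strand-aware gene interval (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: str = "0"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class PeakRecord:
    """One ENCODE narrowPeak row (0-based, half-open).

    ``signal_value`` is the fold-enrichment over background (column 7);
    ``summit_offset`` is the point-source offset from ``start`` (column
    10), -1 when the caller did not report a summit, in which case the
    interval midpoint is used downstream.
    """

    chrom: str
    start: int
    end: int
    name: str
    signal_value: float
    score: int = 0
    strand: str = "."
    p_score: float | None = None
    q_score: float | None = None
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak {self.name}: end <= start")
        if not self.signal_value > 0:
            raise ValueError(f"peak {self.name}: signal_value must be positive")
        if self.summit_offset < -1:
            raise ValueError(f"peak {self.name}: summit offset < -1")
        if self.summit_offset >= 0 and self.summit_offset >= self.end - self.start:
            raise ValueError(
                f"peak {self.name}: summit offset {self.summit_offset} outside "
                f"{self.end - self.start} bp interval"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when unreported."""
        if self.summit_offset >= 0:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _check_unique_gene_ids(genes: list[GeneAnnotation]) -> None:
    seen: dict[str, int] = {}
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate gene_id(s): {dups}")


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Read gene intervals from BED6 or a minimal GTF (gene features only).

    The format is chosen by extension (.gtf/.gff) or by sniffing the first
    data line.  GTF 1-based closed coordinates are converted to 0-based
    half-open on input.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    is_gtf = path.suffix.lower() in (".gtf", ".gff") or any(
        "\tgene\t" in ln for ln in text[:50] if ln and not ln.startswith("#")
    )
    genes: list[GeneAnnotation] = []
    for lineno, line in enumerate(text, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        try:
            if is_gtf:
                if len(cols) < 9:
                    raise ValueError(f"expected 9 GTF columns, got {len(cols)}")
                if cols[2] != "gene":
                    continue
                gene_id = _gtf_attribute(cols[8], "gene_id")
                genes.append(
                    GeneAnnotation(
                        gene_id=gene_id,
                        chrom=cols[0],
                        start=int(cols[3]) - 1,   # 1-based closed -> 0-based half-open
                        end=int(cols[4]),
                        strand=cols[6],
                        score=cols[5],
                    )
                )
            else:
                if len(cols) < 6:
                    raise ValueError(f"expected 6 BED columns, got {len(cols)}")
                genes.append(
                    GeneAnnotation(
                        gene_id=cols[3],
                        chrom=cols[0],
                        start=int(cols[1]),
                        end=int(cols[2]),
                        strand=cols[5],
                        score=cols[4],
                    )
                )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    _check_unique_gene_ids(genes)
    return genes


def _gtf_attribute(attrs: str, key: str) -> str:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key):
            return chunk[len(key):].strip().strip('"')
    raise ValueError(f"missing {key} attribute")


def write_gene_annotation_bed(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.score}\t{g.strand}\n")


def read_narrowpeak(path) -> list[PeakRecord]:
    """Read a 10-column ENCODE narrowPeak file."""
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 10:
                raise ValueError(f"{path}:{lineno}: expected 10 columns, got {len(cols)}")
            try:
                p_score = float(cols[7])
                q_score = float(cols[8])
                peaks.append(
                    PeakRecord(
                        chrom=cols[0],
                        start=int(cols[1]),
                        end=int(cols[2]),
                        name=cols[3],
                        score=int(cols[4]),
                        strand=cols[5],
                        signal_value=float(cols[6]),
                        p_score=None if p_score == -1 else p_score,
                        q_score=None if q_score == -1 else q_score,
                        summit_offset=int(cols[9]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks: list[PeakRecord], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        p.strand,
                        f"{p.signal_value:g}",
                        "-1" if p.p_score is None else f"{p.p_score:g}",
                        "-1" if p.q_score is None else f"{p.q_score:g}",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# count matrix & sample sheet
# ---------------------------------------------------------------------------


def read_count_matrix(path) -> pd.DataFrame:
    """Read a genes x samples raw count TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene_id(s) in count matrix: {dups}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count matrix header")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if np.any(arr < 0):
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("count matrix contains non-integer entries")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path, paired: bool = False) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, patient_id, tissue, dataset_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(df, paired=paired)


def validate_sample_sheet(df: pd.DataFrame, paired: bool = False) -> pd.DataFrame:
    required = ["sample_id", "patient_id", "tissue", "dataset_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    bad = sorted(set(df["tissue"]) - set(TISSUES))
    if bad:
        raise ValueError(f"unknown tissue label(s): {bad}; expected {TISSUES}")
    if paired:
        for ds, grp in df.groupby("dataset_id"):
            ul = set(grp.loc[grp.tissue == "UL", "patient_id"])
            mm = set(grp.loc[grp.tissue == "MM", "patient_id"])
            unmatched = sorted(ul.symmetric_difference(mm))
            if unmatched:
                raise ValueError(
                    f"dataset {ds}: patients without a matched UL/MM pair: {unmatched}"
                )
    return df.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: set name, description, then member gene ids."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
            name, desc, members = cols[0], cols[1], [m for m in cols[2:] if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                warnings.warn(f"{path}:{lineno}: dropping empty gene set {name!r}")
                continue
            # drop within-set duplicates, preserving order
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables and generic results tables
# ---------------------------------------------------------------------------


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format qPCR Ct table: patient_id, gene, tissue, ct.

    Replicate measurements are separate rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "gene": str, "tissue": str})
    required = ["patient_id", "gene", "tissue", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad = sorted(set(df["tissue"]) - set(TISSUES))
    if bad:
        raise ValueError(f"unknown tissue label(s) in Ct table: {bad}")
    df["ct"] = df["ct"].astype(float)
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def write_results_table(records: pd.DataFrame, path) -> None:
    """Write an analysis results table as TSV (round-trip stable)."""
    records.to_csv(path, sep="\t", index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
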