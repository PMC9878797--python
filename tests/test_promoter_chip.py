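"""Promoter windows, peak assignment, enrichment matrix, differential peaks."""

import numpy as np
import pandas as pd
import pytest

from promark.formats_io import GeneAnnotation, PeakRecord
from promark.promoter_chip import (
    EnrichmentMatrix,
    assign_peaks_to_promoters,
    build_enrichment_matrix,
    compute_tss,
    differential_peak_enrichment,
    global_h3k4me3_comparison,
    promoter_window,
)


def peak(chrom, start, end, name="p", signal=2.0, summit=-1):
    return PeakRecord(chrom, start, end, name, signal, summit_offset=summit)


def chip_sheet(n_pairs):
    rows = []
    for i in range(n_pairs):
        for t in ("UL", "MM"):
            rows.append({"sample_id": f"{t}_{i}", "patient_id": f"p{i}",
                         "tissue": t, "dataset_id": "chip"})
    return pd.DataFrame(rows)


class TestTSS:
    def test_plus_strand_uses_start(self):
        assert compute_tss(GeneAnnotation("g", "chr1", 1000, 5000, "+")) == 1000

    def test_minus_strand_uses_last_base(self):
        assert compute_tss(GeneAnnotation("g", "chr1", 1000, 5000, "-")) == 4999

    def test_strand_flip_mirrors_tss(self):
        # a gene placed symmetrically about position c has mirrored TSSs
        plus = GeneAnnotation("a", "chr1", 1000, 5000, "+")
        minus = GeneAnnotation("b", "chr1", 1000, 5000, "-")
        c = (1000 + 4999) / 2
        assert compute_tss(plus) - c == -(compute_tss(minus) - c)

    def test_window_clipped_at_zero(self):
        w = promoter_window(GeneAnnotation("g", "chr1", 500, 2000, "+"), flank=2000)
        assert w.window_start == 0 and w.window_end == 2500 and w.tss == 500


class TestAssignment:
    GENES = [GeneAnnotation("gA", "chr1", 10_000, 20_000, "+")]

    def assign_one(self, pk, **kw):
        df = assign_peaks_to_promoters([pk], self.GENES, **kw)
        return df.iloc[0]

    def test_inside_window_with_distance(self):
        row = self.assign_one(peak("chr1", 11_900, 12_100, summit=99))  # summit 11999
        assert row.gene_id == "gA" and row.distance_to_tss == 1999

    def test_beyond_flank_unassigned(self):
        row = self.assign_one(peak("chr1", 12_001, 12_401, summit=0))  # summit 12001
        assert row.gene_id is None

    def test_closed_boundary_included(self):
        row = self.assign_one(peak("chr1", 11_900, 12_100, summit=100))  # summit 12000
        assert row.gene_id == "gA" and row.distance_to_tss == 2000

    def test_upstream_distance_negative(self):
        row = self.assign_one(peak("chr1", 9_400, 9_600, summit=100))  # summit 9500
        assert row.distance_to_tss == -500

    def test_minus_strand_orientation(self):
        genes = [GeneAnnotation("gB", "chr1", 10_000, 20_000, "-")]  # TSS 19999
        df = assign_peaks_to_promoters([peak("chr1", 20_400, 20_600, summit=100)], genes)
        # summit 20500 is downstream in genome but upstream of the - gene
        assert df.iloc[0].distance_to_tss == -501

    def test_strand_mirror_symmetry(self):
        """Mirroring all coordinates and flipping strands preserves pairs."""
        size = 1_000_000
        genes = [GeneAnnotation("gA", "chr1", 50_000, 60_000, "+")]
        pks = [peak("chr1", 49_000, 49_400, summit=200)]
        fwd = assign_peaks_to_promoters(pks, genes)
        m_genes = [GeneAnnotation("gA", "chr1", size - 60_000, size - 50_000, "-")]
        m_pks = [peak("chr1", size - 49_400, size - 49_000, summit=199)]
        mirror = assign_peaks_to_promoters(m_pks, m_genes)
        assert (fwd.gene_id == mirror.gene_id).all()
        assert np.allclose(fwd.distance_to_tss, mirror.distance_to_tss)

    def test_anchor_midpoint_and_any_overlap(self):
        # window [8000, 12000]; summit 12290 outside, midpoint 12000 on boundary
        pk = peak("chr1", 11_700, 12_300, summit=590)
        assert self.assign_one(pk).gene_id is None
        assert self.assign_one(pk, anchor="midpoint").gene_id == "gA"
        assert self.assign_one(pk, anchor="any-overlap").gene_id == "gA"


class TestEnrichmentMatrix:
    def test_single_sample_standardized(self):
        pks = [peak("chr1", i * 1000, i * 1000 + 400, f"p{i}", s)
               for i, s in enumerate([1.0, 2.0, 3.0])]
        m = build_enrichment_matrix({"s1": pks})
        assert np.allclose(m.values["s1"], [-1, 0, 1])

    def test_identical_samples_identical_columns(self):
        pks = [peak("chr1", i * 1000, i * 1000 + 400, f"p{i}", s)
               for i, s in enumerate([1.0, 5.0, 2.0])]
        m = build_enrichment_matrix({"s1": pks, "s2": list(pks)})
        assert np.allclose(m.values["s1"], m.values["s2"])

    def test_scale_invariance_per_sample(self):
        pks = [peak("chr1", i * 1000, i * 1000 + 400, f"p{i}", s)
               for i, s in enumerate([1.0, 5.0, 2.0])]
        scaled = [PeakRecord(p.chrom, p.start, p.end, p.name, p.signal_value * 10,
                             summit_offset=p.summit_offset) for p in pks]
        m1 = build_enrichment_matrix({"s1": pks})
        m2 = build_enrichment_matrix({"s1": scaled})
        assert np.allclose(m1.values["s1"], m2.values["s1"])

    def test_missing_peak_zero_filled_before_standardization(self):
        full = [peak("chr1", i * 1000, i * 1000 + 400, f"p{i}", 2.0) for i in range(3)]
        partial = full[:2]
        m = build_enrichment_matrix({"s1": full, "s2": partial}, standardize=False)
        assert m.values.loc[m.values.index[2], "s2"] == 0.0

    def test_empty_sample_excluded_with_warning(self):
        pks = [peak("chr1", 0, 400, "p0", 1.0), peak("chr1", 1000, 1400, "p1", 3.0)]
        with pytest.warns(UserWarning, match="no detected peaks"):
            m = build_enrichment_matrix({"s1": pks, "s2": []})
        assert "s2" in m.excluded_samples and list(m.values.columns) == ["s1"]

    def test_standardized_columns_median_zero_sd_one(self):
        rng = np.random.default_rng(0)
        pks = {f"s{j}": [peak("chr1", i * 1000, i * 1000 + 400, f"p{i}",
                              float(rng.lognormal(1, 0.5)))
                         for i in range(21)] for j in range(4)}
        m = build_enrichment_matrix(pks)
        med = m.values.median(axis=0)
        sd = m.values.std(axis=0, ddof=1)
        assert np.allclose(med, 0.0, atol=1e-12)
        assert np.allclose(sd, 1.0, atol=1e-9)


def make_matrix(values, sheet):
    cols = {s: values[:, i] for i, s in enumerate(sheet["sample_id"])}
    df = pd.DataFrame(cols, index=[f"pk{i}" for i in range(values.shape[0])])
    return EnrichmentMatrix(values=df, provenance="standardized")


class TestGlobalComparison:
    def test_identical_tissues_p_one_direction_zero(self):
        sheet = chip_sheet(3)
        rng = np.random.default_rng(1)
        col = rng.normal(size=50)
        vals = np.tile(col[:, None], (1, 6))
        gc = global_h3k4me3_comparison(make_matrix(vals, sheet), sheet)
        assert gc.test.p_value == pytest.approx(1.0)
        assert gc.direction == pytest.approx(0.0)

    def test_label_swap_flips_direction(self):
        sheet = chip_sheet(4)
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(100, 8))
        vals[:, [i for i, t in enumerate(sheet.tissue) if t == "UL"]] += 0.3
        gc = global_h3k4me3_comparison(make_matrix(vals, sheet), sheet)
        swapped = sheet.copy()
        swapped["tissue"] = swapped["tissue"].map({"UL": "MM", "MM": "UL"})
        gc2 = global_h3k4me3_comparison(make_matrix(vals, swapped), swapped)
        assert gc.direction == pytest.approx(-gc2.direction)
        assert gc.test.p_value == pytest.approx(gc2.test.p_value)

    def test_missing_tissue_rejected(self):
        sheet = chip_sheet(3)
        ul_only = sheet[sheet.tissue == "UL"].reset_index(drop=True)
        vals = np.random.default_rng(3).normal(size=(20, 3))
        with pytest.raises(ValueError, match="tissue"):
            global_h3k4me3_comparison(make_matrix(vals, ul_only), ul_only)


class TestDifferentialPeaks:
    def _planted(self, seed, n_peaks=600, n_true=50, n_pairs=8, shift=1.0):
        rng = np.random.default_rng(seed)
        sheet = chip_sheet(n_pairs)
        base = rng.normal(0, 1, size=(n_peaks, 1))
        pat = rng.normal(0, 0.3, size=(n_peaks, n_pairs))
        vals = np.empty((n_peaks, 2 * n_pairs))
        for j, (_, row) in enumerate(sheet.iterrows()):
            pi = int(row.patient_id[1:])
            noise = rng.normal(0, 0.4, n_peaks)
            delta = np.where(np.arange(n_peaks) < n_true, shift, 0.0) if row.tissue == "UL" else 0.0
            vals[:, j] = base[:, 0] + pat[:, pi] + delta + noise
        return make_matrix(vals, sheet), sheet

    def test_planted_shift_recovered(self):
        sens, prec = [], []
        for seed in range(3):
            m, sheet = self._planted(seed)
            res = differential_peak_enrichment(m, sheet, paired=True)
            called = res["q_value"] < 0.05
            truth = res["peak_id"].str.replace("pk", "").astype(int) < 50
            sens.append((called & truth).sum() / truth.sum())
            prec.append((called & truth).sum() / max(called.sum(), 1))
        assert np.mean(sens) >= 0.8 and np.mean(prec) >= 0.9

    def test_shuffled_labels_controls_fdr(self):
        fracs = []
        for seed in range(5):
            m, sheet = self._planted(seed, n_true=0)
            res = differential_peak_enrichment(m, sheet, paired=True)
            fracs.append((res["q_value"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_zero_variance_peak_dominates(self):
        sheet = chip_sheet(4)
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(30, 8))
        ul_cols = [i for i, t in enumerate(sheet.tissue) if t == "UL"]
        mm_cols = [i for i, t in enumerate(sheet.tissue) if t == "MM"]
        vals[0, ul_cols] = 4.0
        vals[0, mm_cols] = 0.0
        res = differential_peak_enrichment(make_matrix(vals, sheet), sheet, paired=False)
        assert res.sort_values("q_value").iloc[0]["peak_id"] == "pk0"

    def test_incomplete_pairs_rejected(self):
        m, sheet = self._planted(0, n_peaks=20, n_pairs=4)
        broken = sheet.drop(index=0).reset_index(drop=True)
        m2 = EnrichmentMatrix(values=m.values[broken.sample_id], provenance="standardized")
        with pytest.raises(ValueError, match="incomplete pairs"):
            differential_peak_enrichment(m2, broken, paired=True)

    def test_direction_matches_delta_sign(self):
        m, sheet = self._planted(1, n_peaks=100, n_true=10)
        res = differential_peak_enrichment(m, sheet)
        assert (np.sign(res.loc[res.direction == "hyper", "delta"]) > 0).all()
        assert (np.sign(res.loc[res.direction == "hypo", "delta"]) < 0).all()
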