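"""Differential-expression statistics and the consensus/intersection rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from promark.consensus_de import (
    DEGSet,
    consensus_degs,
    estimate_dispersion,
    intersect_datasets,
    log_cpm,
    logcpm_moderated_test,
    nb_exact_test,
    nb_wald_test,
    size_factors_median_ratio,
)


def make_sheet(n_pairs, dataset="d1"):
    rows = []
    for i in range(n_pairs):
        for tissue in ("UL", "MM"):
            rows.append(
                {
                    "sample_id": f"{tissue}_{i}",
                    "patient_id": f"p{i}",
                    "tissue": tissue,
                    "dataset_id": dataset,
                }
            )
    return pd.DataFrame(rows)


def nb_counts(rng, n_genes, n_pairs, mu=100.0, disp=0.1, lfc=None):
    """NB count matrix; lfc (per gene) applied half-up/half-down by tissue."""
    sheet = make_sheet(n_pairs)
    mu_g = np.full(n_genes, mu) if np.isscalar(mu) else mu
    lfc = np.zeros(n_genes) if lfc is None else lfc
    cols = {}
    for _, row in sheet.iterrows():
        sign = 0.5 if row.tissue == "UL" else -0.5
        mean = mu_g * 2.0 ** (sign * lfc)
        if disp > 0:
            r = 1.0 / disp
            cols[row.sample_id] = rng.negative_binomial(r, r / (r + mean))
        else:
            cols[row.sample_id] = rng.poisson(mean)
    counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return counts, sheet


class TestSizeFactors:
    def test_doubled_sample_hand_computation(self):
        c = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}, index=list("abc"))
        sf = size_factors_median_ratio(c)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_identical_samples_unit_factors(self):
        c = pd.DataFrame({"s1": [5, 9, 2], "s2": [5, 9, 2]}, index=list("abc"))
        assert np.allclose(size_factors_median_ratio(c), 1.0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(
            rng.poisson(50, size=(30, 4)), columns=list("wxyz"),
            index=[f"g{i}" for i in range(30)],
        ) + 1
        perm = c.sample(frac=1.0, random_state=1)
        assert np.allclose(size_factors_median_ratio(c), size_factors_median_ratio(perm))

    def test_no_universally_expressed_gene(self):
        c = pd.DataFrame({"s1": [0, 3], "s2": [4, 0]}, index=list("ab"))
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors_median_ratio(c)


class TestDispersion:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(1)
        counts, sheet = nb_counts(rng, 5000, 5, mu=100.0, disp=0.0)
        sf = size_factors_median_ratio(counts)
        common, _ = estimate_dispersion(counts, sheet, sf)
        assert common <= 0.02

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(2)
        counts, sheet = nb_counts(rng, 2000, 5, mu=200.0, disp=0.4)
        sf = size_factors_median_ratio(counts)
        common, _ = estimate_dispersion(counts, sheet, sf)
        assert 0.3 <= common <= 0.5

    def test_constant_counts_zero_dispersion(self):
        counts = pd.DataFrame(
            {f"{t}_{i}": [7, 13] for i in range(3) for t in ("UL", "MM")},
            index=["g0", "g1"],
        )
        sheet = make_sheet(3)
        sf = size_factors_median_ratio(counts)
        common, per_gene = estimate_dispersion(counts, sheet, sf)
        assert common == 0.0 and np.allclose(per_gene, 0.0)

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame(
            {"UL_0": [5], "MM_0": [5], "MM_1": [5]},
            index=["g0"],
        )
        sheet = pd.DataFrame(
            {
                "sample_id": ["UL_0", "MM_0", "MM_1"],
                "patient_id": ["p0", "p0", "p1"],
                "tissue": ["UL", "MM", "MM"],
                "dataset_id": "d",
            }
        )
        with pytest.raises(ValueError, match="2 samples"):
            estimate_dispersion(counts, sheet, size_factors_median_ratio(counts))


class TestNBExact:
    def test_balanced_split_p_one(self):
        counts = pd.DataFrame(
            {"UL_0": [10], "MM_0": [10], "UL_1": [10], "MM_1": [10]},
            index=["g0"],
        )
        sheet = make_sheet(2)
        sf = pd.Series(1.0, index=counts.columns)
        res = nb_exact_test(counts, sheet, sf, 0.1)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["log2FC"].iloc[0] == pytest.approx(0.0)

    def test_zero_dispersion_matches_binomial_oracle(self):
        """With alpha = 0 the conditional split is Binomial(T, n_a/(n_a+n_b))."""
        rng = np.random.default_rng(3)
        counts, sheet = nb_counts(rng, 200, 2, mu=8.0, disp=0.0)
        sf = pd.Series(1.0, index=counts.columns)
        res = nb_exact_test(counts, sheet, sf, 0.0)
        ul_cols = [c for c in counts.columns if c.startswith("UL")]
        mm_cols = [c for c in counts.columns if c.startswith("MM")]
        for i, (_, row) in enumerate(counts.iterrows()):
            t = int(row.sum())
            if t == 0 or t > 50:
                continue
            ya = int(row[ul_cols].sum())
            pmf = sps.binom.pmf(np.arange(t + 1), t, 0.5)
            expected = pmf[pmf <= pmf[ya] * (1 + 1e-8)].sum()
            assert res["p_value"].iloc[i] == pytest.approx(expected, rel=1e-6)

    def test_null_type_i_error(self):
        rng = np.random.default_rng(4)
        counts, sheet = nb_counts(rng, 2000, 4, mu=100.0, disp=0.1)
        sf = size_factors_median_ratio(counts)
        res = nb_exact_test(counts, sheet, sf, 0.1)
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_negative_dispersion_rejected(self):
        counts = pd.DataFrame({"UL_0": [1], "MM_0": [1]}, index=["g0"])
        sheet = make_sheet(1)
        with pytest.raises(ValueError, match="dispersion"):
            nb_exact_test(counts, sheet, pd.Series(1.0, index=counts.columns), -0.1)


class TestNBWald:
    def test_identical_groups_null(self):
        counts = pd.DataFrame(
            {"UL_0": [50], "MM_0": [50], "UL_1": [50], "MM_1": [50]},
            index=["g0"],
        )
        sheet = make_sheet(2)
        res = nb_wald_test(counts, sheet, pd.Series(1.0, index=counts.columns), 0.05)
        assert res["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_recovers_planted_effect(self):
        # effects on a 10% minority so normalization stays anchored; the
        # low-dispersion/high-count regime keeps the NB sampling SE of
        # log2FC (~1.44 * sqrt(2(1/mu + alpha)/n)) well below the 0.2 band
        rng = np.random.default_rng(5)
        n = 1000
        lfc = np.zeros(n)
        lfc[:100] = 2.0
        counts, sheet = nb_counts(rng, n, 5, mu=2000.0, disp=0.01, lfc=lfc)
        sf = size_factors_median_ratio(counts)
        res = nb_wald_test(counts, sheet, sf, 0.01)
        ok = np.abs(res["log2FC"].to_numpy()[:100] - 2.0) <= 0.2
        assert ok.mean() >= 0.9

    def test_sign_agreement_with_exact_test(self):
        rng = np.random.default_rng(6)
        lfc = rng.choice([-2.0, 0.0, 2.0], size=400)
        counts, sheet = nb_counts(rng, 400, 5, mu=300.0, disp=0.05, lfc=lfc)
        sf = size_factors_median_ratio(counts)
        disp = 0.05
        exact = nb_exact_test(counts, sheet, sf, disp)
        wald = nb_wald_test(counts, sheet, sf, disp)
        strong = exact["q_value"] < 0.01
        assert (
            np.sign(exact.loc[strong, "log2FC"]) == np.sign(wald.loc[strong, "log2FC"])
        ).all()


class TestLogCPMModerated:
    def test_library_scaling_invariance(self):
        rng = np.random.default_rng(7)
        counts, sheet = nb_counts(rng, 300, 4, mu=200.0, disp=0.05)
        doubled = counts.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        r1 = logcpm_moderated_test(counts, sheet, size_factors_median_ratio(counts))
        r2 = logcpm_moderated_test(doubled, sheet, size_factors_median_ratio(doubled))
        assert np.allclose(r1["log2FC"], r2["log2FC"], atol=0.02)

    def test_null_fdr(self):
        rng = np.random.default_rng(8)
        fracs = []
        for _ in range(5):
            counts, sheet = nb_counts(rng, 1000, 5, mu=100.0, disp=0.1)
            res = logcpm_moderated_test(counts, sheet, size_factors_median_ratio(counts))
            fracs.append((res["q_value"] < 0.01).mean())
        assert np.mean(fracs) <= 0.01

    def test_planted_sensitivity(self):
        rng = np.random.default_rng(9)
        n = 1000
        lfc = np.zeros(n)
        lfc[:100] = 3.0
        counts, sheet = nb_counts(rng, n, 10, mu=150.0, disp=0.05, lfc=lfc)
        res = logcpm_moderated_test(counts, sheet, size_factors_median_ratio(counts))
        sens = (res["q_value"].to_numpy()[:100] < 0.01).mean()
        assert sens >= 0.9


class TestConsensus:
    @staticmethod
    def _method(genes, sig_idx, lfc_val, tag):
        n = len(genes)
        q = np.full(n, 0.5)
        q[sig_idx] = 0.001
        lfc = np.zeros(n)
        lfc[sig_idx] = lfc_val
        return pd.DataFrame(
            {"gene_id": genes, "log2FC": lfc, "p_value": q, "q_value": q, "method": tag}
        )

    def test_two_of_three_excluded_by_default(self):
        genes = [f"g{i}" for i in range(5)]
        r1 = self._method(genes, [0], 2.0, "a")
        r2 = self._method(genes, [0], 2.0, "b")
        r3 = self._method(genes, [], 2.0, "c")
        degs = consensus_degs([r1, r2, r3])
        assert degs.up == set()
        degs_maj = consensus_degs([r1, r2, r3], rule="majority")
        assert degs_maj.up == {"g0"}

    def test_all_three_agree_included(self):
        genes = [f"g{i}" for i in range(4)]
        rs = [self._method(genes, [1], 1.2, t) for t in "abc"]
        degs = consensus_degs(rs)
        assert degs.up == {"g1"} and degs.down == set()

    def test_consensus_no_larger_than_any_method(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(200)]
        rs = []
        for t in "abc":
            q = rng.random(200) * 0.05
            lfc = rng.normal(0, 2, 200)
            rs.append(pd.DataFrame(
                {"gene_id": genes, "log2FC": lfc, "p_value": q, "q_value": q, "method": t}
            ))
        degs = consensus_degs(rs)
        for r in rs:
            per_method = ((r["q_value"] < 0.01) & (r["log2FC"].abs() > 1)).sum()
            assert degs.n_degs <= per_method

    def test_mismatched_universe_rejected(self):
        r1 = self._method(["g0", "g1"], [0], 2.0, "a")
        r2 = self._method(["g0", "g2"], [0], 2.0, "b")
        with pytest.raises(ValueError, match="universe"):
            consensus_degs([r1, r2])

    def test_gene_and_sample_order_invariance(self):
        rng = np.random.default_rng(11)
        lfc = np.zeros(300)
        lfc[:30] = 2.5
        counts, sheet = nb_counts(rng, 300, 5, mu=200.0, disp=0.05, lfc=lfc)
        from promark.pipeline import run_de_cohort

        degs1, _ = run_de_cohort(counts, sheet, "d")
        perm = counts.sample(frac=1.0, random_state=3)[list(counts.columns[::-1])]
        degs2, _ = run_de_cohort(perm, sheet, "d")
        assert degs1.up == degs2.up and degs1.down == degs2.down


class TestIntersect:
    def test_hand_example(self):
        a = DEGSet("A", up={"g1", "g2"}, down={"g4"})
        b = DEGSet("B", up={"g2", "g3"}, down={"g4"})
        shared = intersect_datasets(a, b)
        assert shared.up == {"g2"} and shared.down == {"g4"}

    def test_disjoint_sets_empty(self):
        shared = intersect_datasets(DEGSet("A", up={"g1"}), DEGSet("B", up={"g2"}))
        assert shared.n_degs == 0

    def test_opposite_directions_reported_discordant(self):
        a = DEGSet("A", up={"g1"}, down=set())
        b = DEGSet("B", up=set(), down={"g1"})
        shared = intersect_datasets(a, b)
        assert shared.n_degs == 0 and shared.discordant == {"g1"}

    def test_up_down_overlap_rejected(self):
        with pytest.raises(ValueError, match="both"):
            DEGSet("A", up={"g1"}, down={"g1"})
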