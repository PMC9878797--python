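"""Consensus differential expression between tumor (UL) and normal (MM).

Three re-implemented differential-expression statistics are run on the
same raw count matrix and a gene is only called a DEG when all of them
(or, optionally, a majority) agree on significance and direction:

* ``nb_exact_test`` — conditional negative-binomial exact test on
  library-equalized group totals (classic edgeR-style exact test).
* ``nb_wald_test`` — per-group NB maximum-likelihood means at fixed
  dispersion with a Wald test on the log ratio (DESeq2-style).
* ``logcpm_moderated_test`` — moderated t-statistics on log2 CPM
  (limma-style), via :func:`promark.stats_core.fit_moderated_linear_model`.

These are deliberately simplified relative to the packages that inspired
them (no TMM, no dispersion-trend or APL fitting, no voom weights): the
fidelity target is statistical behavior — error control and effect
recovery — not numerical identity with any one tool.

Effects are reported as log2 fold change of UL over MM.  A pseudo-count
of 0.5 is used everywhere a log of counts is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .stats_core import bh_adjust, fit_moderated_linear_model

__all__ = [
    "DEGSet",
    "size_factors_median_ratio",
    "estimate_dispersion",
    "nb_exact_test",
    "nb_wald_test",
    "logcpm_moderated_test",
    "consensus_degs",
    "intersect_datasets",
]

PSEUDO_COUNT = 0.5
#: shrinkage weight constant: w = df / (df + DISPERSION_SHRINK_DF)
DISPERSION_SHRINK_DF = 10.0


@dataclass
class DEGSet:
    """Directional DEG call set for one dataset at given thresholds."""

    dataset_id: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)
    thresholds: tuple = (0.01, 1.0)
    discordant: set = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"genes in both up and down sets: {sorted(overlap)}")

    @property
    def n_degs(self) -> int:
        return len(self.up) + len(self.down)


def _split_groups(sheet: pd.DataFrame, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (UL, MM) over ``sample_ids`` from the sample sheet."""
    tissue = sheet.set_index("sample_id")["tissue"]
    missing = [s for s in sample_ids if s not in tissue.index]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing}")
    lab = np.array([tissue[s] for s in sample_ids])
    ul, mm = lab == "UL", lab == "MM"
    if ul.sum() == 0 or mm.sum() == 0:
        raise ValueError("need at least one sample per tissue")
    return ul, mm


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Only genes expressed in every sample contribute to the per-sample
    median ratio against the geometric-mean pseudo-reference.
    """
    k = counts.to_numpy(dtype=float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene is expressed in all samples; median-ratio size factors "
            "are undefined (pseudo-reference fallback is disabled)"
        )
    logk = np.log(k[all_pos])
    log_ref = logk.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logk - log_ref, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame, sheet: pd.DataFrame, size_factors: pd.Series
) -> tuple[float, pd.Series]:
    """Method-of-moments NB dispersion from normalized counts.

    Per-gene: alpha = max(0, (var - mean) / mean^2), where the variance is
    pooled within the two tissue groups.  The common dispersion is a 20%
    trimmed mean of per-gene estimates; per-gene values are shrunk toward
    it with weight w = df / (df + 10).

    Returns (common_dispersion, per_gene_dispersion).
    """
    ul, mm = _split_groups(sheet, counts.columns)
    if ul.sum() < 2 or mm.sum() < 2:
        raise ValueError("dispersion estimation needs >= 2 samples per group")
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()
    mean_all = norm.mean(axis=1)
    df_g = (ul.sum() - 1) + (mm.sum() - 1)
    pooled_var = (
        norm[:, ul].var(axis=1, ddof=1) * (ul.sum() - 1)
        + norm[:, mm].var(axis=1, ddof=1) * (mm.sum() - 1)
    ) / df_g
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - mean_all) / mean_all**2
    raw = np.where(mean_all > 0, np.maximum(raw, 0.0), 0.0)
    from scipy.stats import trim_mean

    common = float(trim_mean(raw, 0.2))
    w = df_g / (df_g + DISPERSION_SHRINK_DF)
    shrunk = w * raw + (1.0 - w) * common
    return common, pd.Series(shrunk, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


def _nb_logpmf(k, r, mean):
    """log NB pmf with size r and mean; k, r, mean broadcastable arrays."""
    return (
        special.gammaln(k + r)
        - special.gammaln(r)
        - special.gammaln(k + 1)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def _binom_logpmf(k, n, p):
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


def _exact_pvalues(ya: np.ndarray, yb: np.ndarray, na: int, nb: int, disp: np.ndarray) -> np.ndarray:
    """Two-sided conditional exact p-values for group totals ya vs yb.

    Conditions on T = ya + yb: under the null both groups share one mean,
    so the split follows the convolution of NB(na*mu, disp/na) and
    NB(nb*mu, disp/nb) renormalized over 0..T.  p is the total probability
    of splits as or less likely than the observed one.  disp == 0 reduces
    to a conditional binomial split.
    """
    ya = np.asarray(ya, dtype=np.int64)
    yb = np.asarray(yb, dtype=np.int64)
    disp = np.asarray(disp, dtype=float)
    total = ya + yb
    pvals = np.ones(ya.size, dtype=float)
    nonzero = total > 0
    idx_all = np.flatnonzero(nonzero)
    if idx_all.size == 0:
        return pvals

    # chunk genes so each flat enumeration block stays ~2M terms
    lens = total[idx_all] + 1
    order = idx_all  # keep original gene order within chunks
    csum = np.cumsum(lens)
    block_edges = [0]
    target = 2_000_000
    next_cut = target
    for i, c in enumerate(csum):
        if c >= next_cut:
            block_edges.append(i + 1)
            next_cut = c + target
    if block_edges[-1] != idx_all.size:
        block_edges.append(idx_all.size)

    frac_a = na / (na + nb)
    for b0, b1 in zip(block_edges[:-1], block_edges[1:]):
        genes = order[b0:b1]
        t_g = total[genes]
        n_terms = t_g + 1
        seg_start = np.concatenate([[0], np.cumsum(n_terms)[:-1]])
        flat_gene = np.repeat(np.arange(genes.size), n_terms)
        y = np.arange(n_terms.sum(), dtype=np.int64) - np.repeat(seg_start, n_terms)
        t_flat = t_g[flat_gene]
        d_flat = disp[genes][flat_gene]
        mu_flat = t_flat / (na + nb)

        with np.errstate(divide="ignore", invalid="ignore"):
            pois = d_flat <= 0
            logp = np.empty(y.size, dtype=float)
            if pois.any():
                logp[pois] = _binom_logpmf(y[pois].astype(float), t_flat[pois].astype(float), frac_a)
            nb_mask = ~pois
            if nb_mask.any():
                ra = na / d_flat[nb_mask]
                rb = nb / d_flat[nb_mask]
                logp[nb_mask] = _nb_logpmf(
                    y[nb_mask].astype(float), ra, na * mu_flat[nb_mask]
                ) + _nb_logpmf(
                    (t_flat[nb_mask] - y[nb_mask]).astype(float), rb, nb * mu_flat[nb_mask]
                )
        # normalize within each gene segment and sum the "as or less likely" tail
        seg_max = np.maximum.reduceat(logp, seg_start)
        prob = np.exp(logp - seg_max[flat_gene])
        z = np.add.reduceat(prob, seg_start)
        obs_prob = prob[seg_start + ya[genes]]
        le_obs = prob <= obs_prob[flat_gene] * (1.0 + 1e-8)
        tail = np.add.reduceat(np.where(le_obs, prob, 0.0), seg_start)
        pvals[genes] = np.minimum(tail / z, 1.0)
    return pvals


def _normalized_means_and_lfc(counts, size_factors, ul, mm):
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()
    mean_ul = norm[:, ul].mean(axis=1)
    mean_mm = norm[:, mm].mean(axis=1)
    lfc = np.log2(mean_ul + PSEUDO_COUNT) - np.log2(mean_mm + PSEUDO_COUNT)
    return mean_ul, mean_mm, lfc


def nb_exact_test(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    size_factors: pd.Series,
    dispersion: pd.Series | float,
) -> pd.DataFrame:
    """Conditional NB exact test per gene (UL vs MM).

    Counts are first equalized to a common library size by dividing by the
    size factors; group totals of these pseudo-counts are rounded to
    integers, and the exact conditional split test is applied.
    """
    ul, mm = _split_groups(sheet, counts.columns)
    disp = _per_gene_dispersion(dispersion, counts.index)
    if (disp < 0).any():
        raise ValueError("dispersion must be non-negative")
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()
    ya = np.round(norm[:, ul].sum(axis=1)).astype(np.int64)
    yb = np.round(norm[:, mm].sum(axis=1)).astype(np.int64)
    p = _exact_pvalues(ya, yb, int(ul.sum()), int(mm.sum()), disp.to_numpy())
    _, _, lfc = _normalized_means_and_lfc(counts, size_factors, ul, mm)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2FC": lfc,
            "p_value": p,
            "q_value": bh_adjust(p),
            "method": "nb_exact",
        }
    ).reset_index(drop=True)


def _per_gene_dispersion(dispersion, index) -> pd.Series:
    if np.isscalar(dispersion):
        return pd.Series(float(dispersion), index=index)
    return dispersion.reindex(index)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------


def _nb_group_mle(k: np.ndarray, s: np.ndarray, disp: np.ndarray, max_iter: int = 100):
    """Vectorized per-gene NB mean MLE for one group at fixed dispersion.

    Solves the score equation sum_j (k_j/mu - s_j (r + k_j)/(r + mu s_j)) = 0
    by Newton iteration on mu.  Returns (mu_hat, converged).
    """
    tot = k.sum(axis=1)
    s_tot = s.sum()
    mu = np.maximum(tot / s_tot, 1e-8)
    converged = np.zeros(mu.size, dtype=bool)
    zero = tot == 0
    mu[zero] = 1e-8
    converged[zero] = True
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        r = np.where(disp > 0, 1.0 / np.maximum(disp, 1e-300), np.inf)
        for _ in range(max_iter):
            active = ~converged
            if not active.any():
                break
            mu_a = mu[active][:, None]
            r_a = r[active][:, None]
            k_a = k[active]
            denom = r_a + mu_a * s[None, :]
            # Poisson limit (r = inf): score = sum(k)/mu - sum(s)
            inf_r = ~np.isfinite(r_a[:, 0])
            score = (k_a / mu_a - s[None, :] * (r_a + k_a) / denom).sum(axis=1)
            d_score = (-k_a / mu_a**2 + s[None, :] ** 2 * (r_a + k_a) / denom**2).sum(axis=1)
            if inf_r.any():
                score[inf_r] = k_a[inf_r].sum(axis=1) / mu_a[inf_r, 0] - s_tot
                d_score[inf_r] = -k_a[inf_r].sum(axis=1) / mu_a[inf_r, 0] ** 2
            step = np.where(d_score != 0, score / d_score, 0.0)
            new = np.maximum(mu[active] - step, mu[active] * 0.1)
            done = np.abs(new - mu[active]) <= 1e-10 + 1e-8 * new
            mu[active] = new
            conv_idx = np.flatnonzero(active)[done]
            converged[conv_idx] = True
    return mu, converged


def nb_wald_test(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    size_factors: pd.Series,
    dispersion: pd.Series | float,
) -> pd.DataFrame:
    """Wald test on the log ratio of per-group NB maximum-likelihood means.

    The dispersion is held fixed; the standard error comes from the Fisher
    information of log(mu) per group.  Genes whose mean fit does not
    converge get a missing p-value.
    """
    ul, mm = _split_groups(sheet, counts.columns)
    disp = _per_gene_dispersion(dispersion, counts.index).to_numpy()
    if (disp < 0).any():
        raise ValueError("dispersion must be non-negative")
    k = counts.to_numpy(dtype=float)
    s = size_factors.to_numpy(dtype=float)

    mu_a, conv_a = _nb_group_mle(k[:, ul], s[ul], disp)
    mu_b, conv_b = _nb_group_mle(k[:, mm], s[mm], disp)
    converged = conv_a & conv_b

    with np.errstate(divide="ignore", invalid="ignore"):
        info_a = (mu_a[:, None] * s[ul][None, :] / (1.0 + disp[:, None] * mu_a[:, None] * s[ul][None, :])).sum(axis=1)
        info_b = (mu_b[:, None] * s[mm][None, :] / (1.0 + disp[:, None] * mu_b[:, None] * s[mm][None, :])).sum(axis=1)
        se = np.sqrt(1.0 / info_a + 1.0 / info_b)
        theta = np.log(mu_a) - np.log(mu_b)
        z = theta / se
    p = 2.0 * special.ndtr(-np.abs(z))
    p = np.where(converged, p, np.nan)
    # report the same pseudo-count log2FC convention as the exact test
    _, _, lfc = _normalized_means_and_lfc(counts, size_factors, ul, mm)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2FC": lfc,
            "p_value": p,
            "q_value": bh_adjust(p),
            "method": "nb_wald",
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# moderated log-CPM test
# ---------------------------------------------------------------------------


def log_cpm(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2 counts-per-million on size-factor-normalized libraries."""
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()
    lib = norm.sum(axis=0)
    cpm = (norm + PSEUDO_COUNT) / (lib + 1.0)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.index, columns=counts.columns)


def logcpm_moderated_test(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    size_factors: pd.Series,
    paired: bool = False,
) -> pd.DataFrame:
    """Moderated t-test on log2 CPM with a UL-vs-MM contrast.

    With ``paired=True`` the patient is added as a blocking covariate
    (requires complete UL/MM pairs).
    """
    ul, mm = _split_groups(sheet, counts.columns)
    lc = log_cpm(counts, size_factors)
    tissue = ul.astype(float)
    if paired:
        meta = sheet.set_index("sample_id").loc[list(counts.columns)]
        patients = pd.get_dummies(meta["patient_id"], drop_first=True).to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(tissue)), tissue, patients])
        contrast = np.zeros(design.shape[1])
        contrast[1] = 1.0
    else:
        design = np.column_stack([np.ones(len(tissue)), tissue])
        contrast = np.array([0.0, 1.0])
    fit = fit_moderated_linear_model(lc.to_numpy(), design, contrast, feature_ids=lc.index)
    return pd.DataFrame(
        {
            "gene_id": fit["feature_id"],
            "log2FC": fit["effect"],
            "p_value": fit["p_value"],
            "q_value": fit["q_value"],
            "method": "logcpm_moderated",
        }
    )


# ---------------------------------------------------------------------------
# consensus & dataset intersection
# ---------------------------------------------------------------------------


def consensus_degs(
    results: list[pd.DataFrame],
    dataset_id: str = "dataset",
    fdr: float = 0.01,
    min_abs_log2fc: float = 1.0,
    rule: str = "intersection",
) -> DEGSet:
    """Combine per-method DE results into one directional DEG set.

    ``rule='intersection'`` (default) requires q < fdr and |log2FC| >
    min_abs_log2fc with a consistent sign in every method;
    ``rule='majority'`` requires it in at least 2 of the 3 methods.
    Missing p-values count as not significant.
    """
    if rule not in ("intersection", "majority"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    universes = [frozenset(r["gene_id"]) for r in results]
    if len(set(universes)) != 1:
        sym = sorted(set().union(*universes) - set.intersection(*(set(u) for u in universes)))
        raise ValueError(f"methods tested different gene universes; asymmetric genes: {sym[:20]}")
    need = len(results) if rule == "intersection" else 2

    up_votes: dict[str, int] = {}
    down_votes: dict[str, int] = {}
    for r in results:
        sig = (r["q_value"] < fdr) & r["p_value"].notna()
        for g in r.loc[sig & (r["log2FC"] > min_abs_log2fc), "gene_id"]:
            up_votes[g] = up_votes.get(g, 0) + 1
        for g in r.loc[sig & (r["log2FC"] < -min_abs_log2fc), "gene_id"]:
            down_votes[g] = down_votes.get(g, 0) + 1
    up = {g for g, v in up_votes.items() if v >= need}
    down = {g for g, v in down_votes.items() if v >= need}
    # a gene cannot satisfy both directions within one method, but majority
    # voting across methods could in principle; drop such conflicts
    conflict = up & down
    return DEGSet(
        dataset_id=dataset_id,
        up=up - conflict,
        down=down - conflict,
        thresholds=(fdr, min_abs_log2fc),
    )


def intersect_datasets(set_a: DEGSet, set_b: DEGSet) -> DEGSet:
    """Shared DEGs across two cohorts: direction-consistent intersection.

    Genes called in opposite directions in the two cohorts are recorded in
    ``discordant`` and excluded from the shared up/down sets.
    """
    shared_up = set_a.up & set_b.up
    shared_down = set_a.down & set_b.down
    discordant = (set_a.up & set_b.down) | (set_a.down & set_b.up)
    return DEGSet(
        dataset_id=f"{set_a.dataset_id}&{set_b.dataset_id}",
        up=shared_up,
        down=shared_down,
        thresholds=set_a.thresholds,
        discordant=discordant,
    )
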