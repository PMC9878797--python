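"""Statistical primitives used throughout the pipeline.

Everything here is self-contained (numpy/scipy special functions only) so
that each primitive can be checked against a brute-force oracle:

* Benjamini-Hochberg step-up FDR adjustment.
* Wilcoxon rank-sum (Mann-Whitney) test, exact by enumeration for small
  samples, normal approximation with tie correction otherwise.
* Wilcoxon signed-rank and paired t tests for matched designs.
* Upper-tail hypergeometric probability (over-representation statistic).
* Empirical-Bayes moderated linear model: per-feature OLS with residual
  variances shrunk toward a common prior estimated by moment matching on
  log variances (the classic moderated t-statistic).
* PCA by feature-centered SVD with deterministic sign convention.
* Per-sample standardization (value - median) / sd.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import rankdata
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "paired_t_test",
    "hypergeom_tail",
    "fit_moderated_linear_model",
    "pca",
    "standardize_sample",
]

#: prior df value used to represent "infinite" shrinkage
PRIOR_DF_CAP = 1e6


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or paired hypothesis test."""

    statistic: float
    p_value: float
    method: str
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to 1, returned in the
    original order of ``p_values``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    finite = p[~np.isnan(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    q[np.isnan(p)] = np.nan
    return q


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _rank_sum_exact_p(ranks: np.ndarray, n: int, u_obs: float, alternative: str) -> float:
    """Exact p by enumerating all assignments of the pooled (mid)ranks."""
    total = ranks.size
    center = n * (total - n) / 2.0
    base = n * (n + 1) / 2.0
    count = 0
    n_splits = 0
    for combo in itertools.combinations(range(total), n):
        u = ranks[list(combo)].sum() - base
        n_splits += 1
        if alternative == "greater":
            hit = u >= u_obs - 1e-12
        elif alternative == "less":
            hit = u <= u_obs + 1e-12
        else:
            hit = abs(u - center) >= abs(u_obs - center) - 1e-12
        if hit:
            count += 1
    return count / n_splits


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of two independent samples.

    The statistic is U for the first sample.  For n + m <= 10 the p-value
    is exact, by enumeration of all C(n+m, n) assignments of the pooled
    midranks (this handles ties as a rank permutation test); otherwise a
    normal approximation with tie-corrected variance and continuity
    correction is used.  ``alternative`` 'greater' means x tends larger.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0

    if n + m <= 10:
        p = _rank_sum_exact_p(ranks, n, u_obs, alternative)
        return TestResult(u_obs, min(p, 1.0), "wilcoxon_rank_sum_exact", alternative)

    total = n + m
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1.0)))
    if var <= 0:
        return TestResult(u_obs, 1.0, "wilcoxon_rank_sum_normal", alternative)
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(u_obs - mu) - 0.5) / sd
        p = 2.0 * special.ndtr(-max(z, 0.0))
    elif alternative == "greater":
        z = (u_obs - mu - 0.5) / sd
        p = special.ndtr(-z)
    else:
        z = (u_obs - mu + 0.5) / sd
        p = special.ndtr(z)
    return TestResult(u_obs, min(p, 1.0), "wilcoxon_rank_sum_normal", alternative)


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired samples (or on differences).

    Zero differences are dropped.  Exact sign enumeration for <= 12
    informative pairs without tied |differences|; otherwise normal
    approximation with continuity correction.
    """
    d = np.asarray(x, dtype=float).ravel()
    if y is not None:
        d = d - np.asarray(y, dtype=float).ravel()
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", alternative)
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = d.size
    r = rankdata(np.abs(d))
    w_plus = r[d > 0].sum()
    mu = n * (n + 1) / 4.0

    if n <= 12 and np.unique(np.abs(d)).size == n:
        stats = np.array(
            [r[np.array(signs, dtype=bool)].sum()
             for signs in itertools.product((0, 1), repeat=n)]
        )
        if alternative == "greater":
            p = np.mean(stats >= w_plus - 1e-12)
        elif alternative == "less":
            p = np.mean(stats <= w_plus + 1e-12)
        else:
            p = np.mean(np.abs(stats - mu) >= abs(w_plus - mu) - 1e-12)
        return TestResult(w_plus, float(min(p, 1.0)), "wilcoxon_signed_rank_exact", alternative)

    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "wilcoxon_signed_rank_normal", alternative)
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(w_plus - mu) - 0.5) / sd
        p = 2.0 * special.ndtr(-max(z, 0.0))
    elif alternative == "greater":
        p = special.ndtr(-(w_plus - mu - 0.5) / sd)
    else:
        p = special.ndtr((w_plus - mu + 0.5) / sd)
    return TestResult(w_plus, float(min(p, 1.0)), "wilcoxon_signed_rank_normal", alternative)


def paired_t_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Student's paired t-test on matched samples."""
    d = np.asarray(x, dtype=float).ravel() - np.asarray(y, dtype=float).ravel()
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else math.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    if alternative == "two-sided":
        p = 2.0 * t_dist.sf(abs(t), df)
    elif alternative == "greater":
        p = t_dist.sf(t, df)
    elif alternative == "less":
        p = t_dist.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(float(t), float(min(p, 1.0)), "paired_t", alternative)


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------


def _log_binom(n, k):
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def hypergeom_tail(k: int, set_size: int, draw_size: int, universe: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, set_size, draw_size).

    The probability of drawing at least ``k`` members of a set of
    ``set_size`` genes when sampling ``draw_size`` genes without
    replacement from ``universe`` genes.
    """
    k, K, n, N = int(k), int(set_size), int(draw_size), int(universe)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= set_size, draw_size <= universe")
    if not (0 <= k <= min(K, n)):
        raise ValueError("overlap must satisfy 0 <= k <= min(set_size, draw_size)")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    i = np.arange(max(k, lo), hi + 1)
    if i.size == 0:
        return 0.0
    logp = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(special.logsumexp(logp))))


# ---------------------------------------------------------------------------
# moderated linear model
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) from per-feature residual variances.

    Matches the first two moments of log residual variances against the
    scaled-F model: log s^2 = log s0^2 + (chi2_d/d in log space), using the
    digamma/trigamma identities for log chi-square moments.  Returns
    (prior_df, prior_var); prior_df is capped at PRIOR_DF_CAP to represent
    an effectively infinite prior.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return PRIOR_DF_CAP, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_bar = float(e.mean())
    g = e.size
    rhs = float(np.mean((e - e_bar) ** 2) * g / (g - 1) - special.polygamma(1, df / 2.0))
    if rhs <= 1e-10:
        d0 = PRIOR_DF_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(rhs), PRIOR_DF_CAP)
    s0_2 = math.exp(e_bar + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return float(d0), float(s0_2)


def fit_moderated_linear_model(
    matrix,
    design,
    contrast,
    feature_ids=None,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Per-feature OLS with empirical-Bayes variance moderation.

    Parameters
    ----------
    matrix : (features, samples) array of responses (log scale expected).
    design : (samples, covariates) full-rank design matrix.
    contrast : (covariates,) weight vector defining the tested effect.
    prior_df, prior_var : override the estimated hyperparameters
        (``prior_df=0`` recovers the ordinary t-statistic; a very large
        ``prior_df`` pools every feature to ``prior_var``).

    Returns a DataFrame with one row per feature: effect, residual_sd,
    residual_df, prior_df, prior_var, posterior_var, t_moderated, p_value,
    q_value.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2:
        raise ValueError("matrix must be 2-D (features x samples)")
    x = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, p = x.shape
    if y.shape[1] != n:
        raise ValueError("matrix and design disagree on sample count")
    if c.shape != (p,):
        raise ValueError("contrast length must match design columns")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # name the collinear columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        bad = sorted(piv[rank:].tolist())
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ (xtx_inv @ x.T).T          # features x p
    resid = y - beta @ x.T
    s2 = (resid**2).sum(axis=1) / df_resid
    effect = beta @ c
    se_unscaled = math.sqrt(float(c @ xtx_inv @ c))

    if prior_df is None:
        d0, s0_2 = estimate_prior_variance(s2, df_resid)
    else:
        d0 = float(prior_df)
        s0_2 = float(prior_var) if prior_var is not None else estimate_prior_variance(s2, df_resid)[1]
    if d0 > 0 and s0_2 <= 0:
        raise ValueError("prior variance must be positive")

    post_var = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid) if d0 > 0 else s2.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = effect / (se_unscaled * np.sqrt(post_var))
    t_mod = np.where(post_var > 0, t_mod, np.where(effect == 0, 0.0, np.inf * np.sign(effect)))
    df_total = min(d0 + df_resid, PRIOR_DF_CAP)
    p_val = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    q_val = bh_adjust(p_val)

    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(y.shape[0])]
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "effect": effect,
            "residual_sd": np.sqrt(s2),
            "residual_df": float(df_resid),
            "prior_df": d0,
            "prior_var": s0_2,
            "posterior_var": post_var,
            "t_moderated": t_mod,
            "p_value": p_val,
            "q_value": q_val,
        }
    )


# ---------------------------------------------------------------------------
# PCA and standardization
# ---------------------------------------------------------------------------


def pca(matrix, n_components: int | None = None):
    """PCA of samples from a features x samples matrix.

    Features are centered across samples; scores come from the SVD of the
    centered matrix.  Component signs are fixed by making the
    largest-magnitude entry of each loading vector positive.

    Returns (scores, variance_fractions): scores is samples x components,
    variance fractions sum to 1 over the full rank (all zero for a
    constant matrix).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    centered = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    k = s.size if n_components is None else min(n_components, s.size)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(u[:, j])))
        if u[i_max, j] < 0:
            u[:, j] *= -1
            vt[j, :] *= -1
    scores = (vt[:k, :].T * s[:k])
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, frac


def standardize_sample(values) -> np.ndarray:
    """Standardize one sample's values: (v - median(v)) / sd(v).

    Uses the sample standard deviation (n-1 denominator).  Raises if fewer
    than 2 values or if the standard deviation is zero; callers exclude
    such samples with a warning.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("standardization needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("standard deviation is zero; sample cannot be standardized")
    return (v - np.median(v)) / sd
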