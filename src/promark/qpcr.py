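"""ΔΔCt fold-change math for qPCR validation cohorts.

For each patient with both tissues measured, target Ct is normalized to a
housekeeping gene (ΔCt = Ct_target − Ct_housekeeping per tissue), the
tumor/normal contrast is ΔΔCt = ΔCt_UL − ΔCt_MM, and the reported fold
change is 2^(−mean ΔΔCt).  Replicate wells are averaged arithmetically
before any subtraction.  Significance comes from a paired test on the
per-patient ΔCt pairs (paired t by default, Wilcoxon signed-rank by flag).
No amplification-efficiency correction is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import paired_t_test, wilcoxon_signed_rank

__all__ = ["FoldChangeResult", "delta_delta_ct"]


@dataclass(frozen=True)
class FoldChangeResult:
    """ΔΔCt summary for one target gene across a validation cohort."""

    gene: str
    n_patients: int
    mean_delta_delta_ct: float
    fold_change: float
    p_value: float
    test_used: str

    def __post_init__(self) -> None:
        if self.n_patients > 0 and not math.isclose(
            self.fold_change, 2.0 ** (-self.mean_delta_delta_ct), rel_tol=1e-12
        ):
            raise ValueError("fold_change must equal 2^(-mean ΔΔCt)")


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    housekeeping: str = "GAPDH",
    test: str = "paired_t",
) -> FoldChangeResult:
    """Fold change of ``target`` in UL vs MM by the ΔΔCt method.

    ``table`` is a long-format Ct table (patient_id, gene, tissue, ct)
    with replicate rows.  Patients missing the target or housekeeping
    measurement in either tissue are dropped with a warning; with fewer
    than 3 complete patients the p-value is reported missing.
    """
    if test not in ("paired_t", "wilcoxon_signed_rank"):
        raise ValueError(f"unknown test {test!r}")
    sub = table[table["gene"].isin([target, housekeeping])]
    if target not in set(sub["gene"]):
        raise ValueError(f"target gene {target!r} absent from Ct table")
    if housekeeping not in set(sub["gene"]):
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from Ct table")

    # average replicates, then pivot to (patient) x (gene, tissue)
    mean_ct = (
        sub.groupby(["patient_id", "gene", "tissue"])["ct"].mean().unstack(["gene", "tissue"])
    )
    needed = [(target, "UL"), (target, "MM"), (housekeeping, "UL"), (housekeeping, "MM")]
    missing_cols = [c for c in needed if c not in mean_ct.columns]
    if missing_cols:
        raise ValueError(f"no measurements at all for: {missing_cols}")
    complete = mean_ct[needed].dropna()
    dropped = sorted(set(mean_ct.index) - set(complete.index))
    if dropped:
        warnings.warn(
            f"{target}: dropping patient(s) with incomplete Ct measurements: {dropped}"
        )

    n = len(complete)
    if n == 0:
        return FoldChangeResult(target, 0, float("nan"), float("nan"), float("nan"), test)

    d_ct_ul = complete[(target, "UL")] - complete[(housekeeping, "UL")]
    d_ct_mm = complete[(target, "MM")] - complete[(housekeeping, "MM")]
    ddct = (d_ct_ul - d_ct_mm).to_numpy()
    mean_ddct = float(np.mean(ddct))
    fc = 2.0 ** (-mean_ddct)

    if n < 3:
        p = float("nan")
    elif test == "paired_t":
        p = paired_t_test(d_ct_ul.to_numpy(), d_ct_mm.to_numpy()).p_value
    else:
        p = wilcoxon_signed_rank(d_ct_ul.to_numpy(), d_ct_mm.to_numpy()).p_value
    return FoldChangeResult(target, n, mean_ddct, fc, p, test)
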