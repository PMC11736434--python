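"""qPCR relative-expression computation and proximal-usage comparison.

Relative expression of a PAS-specific transcript is the reference-
normalized fold difference RE = eff^(Cq_ref - Cq_assay) with efficiency
2.0 by default (one doubling per cycle), using replicate-mean Cq values.
Comparing the proximal/distal RE ratios between two cell types yields a
shortening or lengthening verdict backed by a Welch t-test on
replicate-level log2 ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CQ_COLUMNS = ["sample", "cell_type", "assay", "replicate", "cq"]


def validate_cq_table(cq: pd.DataFrame, reference: str = "reference") -> None:
    missing = [c for c in CQ_COLUMNS if c not in cq.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    if (cq["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    for (sample, ct), g in cq.groupby(["sample", "cell_type"]):
        if not (g["assay"] == reference).any():
            raise ValueError(f"no {reference!r} assay for sample={sample}, cell_type={ct}")


def compute_relative_expression(
    cq: pd.DataFrame,
    reference: str = "reference",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per (sample, cell_type, assay): RE = eff^(mean Cq_ref - mean Cq_assay).

    Also reports the replicate count and Cq standard deviation.
    """
    validate_cq_table(cq, reference)
    rows = []
    for (sample, ct), g in cq.groupby(["sample", "cell_type"]):
        ref_cq = g.loc[g["assay"] == reference, "cq"].mean()
        for assay, ga in g.groupby("assay"):
            if assay == reference:
                continue
            mean_cq = ga["cq"].mean()
            rows.append(dict(
                sample=sample, cell_type=ct, assay=assay,
                n_replicates=len(ga),
                cq_mean=mean_cq, cq_sd=ga["cq"].std(ddof=1),
                relative_expression=float(efficiency ** (ref_cq - mean_cq)),
            ))
    return pd.DataFrame(rows)


@dataclass
class REComparison:
    cell_type_1: str
    cell_type_2: str
    proximal_ratio: float    # p2 / p1
    distal_ratio: float      # d2 / d1
    composite_ratio: float   # (p2/p1) / (d2/d1)
    p_value: float           # NaN with a single replicate
    verdict: str             # shortening | lengthening | inconclusive


def _replicate_log_ratios(cq: pd.DataFrame, cell_type: str, reference: str,
                          efficiency: float) -> np.ndarray:
    """Per-replicate log2(RE_proximal / RE_distal) within one cell type.

    Reference Cq cancels: the ratio reduces to
    log2(eff) * (Cq_distal - Cq_proximal) per paired replicate.
    """
    g = cq[cq["cell_type"] == cell_type]
    prox = g[g["assay"] == "proximal"].set_index(["sample", "replicate"])["cq"]
    dist = g[g["assay"] == "distal"].set_index(["sample", "replicate"])["cq"]
    common = prox.index.intersection(dist.index)
    return np.log2(efficiency) * (dist.loc[common] - prox.loc[common]).to_numpy()


def compare_re_ppas(
    cq: pd.DataFrame,
    cell_type_1: str,
    cell_type_2: str,
    reference: str = "reference",
    efficiency: float = 2.0,
    alpha: float = 0.05,
) -> REComparison:
    """Proximal-vs-distal RE comparison between two cell types.

    Verdict is shortening in ``cell_type_2`` when the composite ratio
    (p2/p1)/(d2/d1) exceeds 1 with Welch-t p < alpha on replicate-level
    log ratios; lengthening when below 1; otherwise inconclusive.
    """
    validate_cq_table(cq, reference)
    re = compute_relative_expression(cq, reference, efficiency)

    def mean_re(ct: str, assay: str) -> float:
        sel = re[(re["cell_type"] == ct) & (re["assay"] == assay)]
        if sel.empty:
            raise ValueError(f"no {assay} assay for cell type {ct!r}")
        return float(sel["relative_expression"].mean())

    p1, p2 = mean_re(cell_type_1, "proximal"), mean_re(cell_type_2, "proximal")
    d1, d2 = mean_re(cell_type_1, "distal"), mean_re(cell_type_2, "distal")
    prox_ratio, dist_ratio = p2 / p1, d2 / d1
    composite = prox_ratio / dist_ratio

    lr1 = _replicate_log_ratios(cq, cell_type_1, reference, efficiency)
    lr2 = _replicate_log_ratios(cq, cell_type_2, reference, efficiency)
    if lr1.size < 2 or lr2.size < 2:
        p_value = float("nan")
    elif np.array_equal(lr1, lr2):
        p_value = 1.0
    else:
        p_value = float(stats.ttest_ind(lr2, lr1, equal_var=False).pvalue)

    if np.isfinite(p_value) and p_value < alpha and composite > 1:
        verdict = "shortening"
    elif np.isfinite(p_value) and p_value < alpha and composite < 1:
        verdict = "lengthening"
    else:
        verdict = "inconclusive"
    return REComparison(
        cell_type_1=cell_type_1, cell_type_2=cell_type_2,
        proximal_ratio=prox_ratio, distal_ratio=dist_ratio,
        composite_ratio=composite, p_value=p_value, verdict=verdict,
    )
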