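"""Proximal and intronic PAS usage indices.

pPUI of a multi-PAS 3'UTR is log2 of the pseudocounted proximal-peak
count over the geometric mean of all pseudocounted peak counts:

    pPUI = log2[ (C1 + 1) / gmean_j(Cj + 1) ]

iPUI relates one intronic peak to the summed 3'UTR counts of its gene:

    iPUI = log2[ (Ci + 1) / (Cu + 1) ]

Higher pPUI means shorter 3'UTR (proximal preference); higher iPUI means
stronger intronic cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class UTRPeakGroup:
    """Ordered proximal->distal peaks of one multi-PAS 3'UTR.

    ``peak_ids[0]`` is the proximal peak (most upstream in transcription
    order: smallest edge3 on '+', largest on '-').
    """

    gene_id: str
    utr_id: str
    strand: str
    peak_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.peak_ids) < 2:
            raise ValueError("UTRPeakGroup requires >= 2 peaks")


def group_utr_peaks(peaks: pd.DataFrame) -> tuple[list[UTRPeakGroup], int]:
    """Group filtered 3'UTR peaks into multi-PAS units.

    Returns the groups plus the number of single-peak 3'UTRs excluded.
    Peaks of one 3'UTR on mixed strands raise ValueError.
    """
    sub = peaks[peaks["region_class"] == "utr3"]
    groups: list[UTRPeakGroup] = []
    n_single = 0
    utr_key = sub["gene_id"].astype(str)
    for gid, g in sub.groupby(utr_key, sort=True):
        strands = g["strand"].unique()
        if len(strands) > 1:
            raise ValueError(f"3'UTR peaks of {gid} lie on mixed strands")
        if len(g) < 2:
            n_single += 1
            continue
        ordered = g.sort_values("edge3", ascending=strands[0] == "+")
        groups.append(UTRPeakGroup(
            gene_id=gid, utr_id=f"{gid}:utr3", strand=strands[0],
            peak_ids=list(ordered["peak_id"]),
        ))
    return groups, n_single


def ppui_from_counts(counts: np.ndarray) -> float:
    """pPUI of one count vector ordered proximal -> distal."""
    # computed as log2(C1+1) - mean(log2(Cj+1)): identical to dividing by
    # the geometric mean, but exact for symmetric count vectors
    c = np.log2(np.asarray(counts, dtype=float) + 1.0)
    return float(c[0] - np.mean(c))


def compute_ppui(
    groups: list[UTRPeakGroup],
    counts: pd.DataFrame,
) -> pd.DataFrame:
    """Cluster-level pPUI matrix: one row per multi-PAS unit.

    ``counts`` is the peak x cluster count matrix.  Every entry is
    defined (pseudocounts handle zeros at cluster level).
    """
    rows = {}
    for grp in groups:
        sub = counts.loc[grp.peak_ids]
        c = np.log2(sub.to_numpy(dtype=float) + 1.0)
        rows[grp.utr_id] = c[0] - np.mean(c, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)


def compute_ppui_cells(
    groups: list[UTRPeakGroup],
    cell_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Cell-level pPUI matrix with missingness.

    ``cell_counts`` is long form (peak_id, barcode, count).  A unit is
    missing (NaN) in a cell with zero reads across the unit's peaks —
    pseudocounting empty cells would pin pPUI at 0 and fabricate signal.
    """
    wide = (
        cell_counts.pivot_table(index="peak_id", columns="barcode",
                                values="count", aggfunc="sum", fill_value=0)
    )
    rows = {}
    for grp in groups:
        sub = wide.reindex(grp.peak_ids, fill_value=0)
        raw = sub.to_numpy(dtype=float)
        c = np.log2(raw + 1.0)
        vals = c[0] - np.mean(c, axis=0)
        vals[raw.sum(axis=0) == 0] = np.nan
        rows[grp.utr_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=wide.columns)


def compute_ipui(intronic_count, utr_count_sum) -> float | np.ndarray:
    """iPUI = log2[(Ci + 1) / (Cu + 1)]; accepts scalars or arrays."""
    ci = np.asarray(intronic_count, dtype=float)
    cu = np.asarray(utr_count_sum, dtype=float)
    out = np.log2(ci + 1.0) - np.log2(cu + 1.0)
    return float(out) if out.ndim == 0 else out


def compute_ipui_matrix(
    peaks: pd.DataFrame,
    counts: pd.DataFrame,
) -> pd.DataFrame:
    """iPUI per intronic peak x cluster.

    A gene with several intronic peaks yields one unit per peak; Cu is
    the sum of the gene's 3'UTR peak counts in the same column.
    """
    utr = peaks[peaks["region_class"] == "utr3"]
    intr = peaks[peaks["region_class"] == "intron"]
    utr_sum = (
        counts.loc[utr["peak_id"]]
        .groupby(utr["gene_id"].to_numpy())
        .sum()
    )
    rows = {}
    for _, pk in intr.iterrows():
        ci = counts.loc[pk["peak_id"]].to_numpy(dtype=float)
        if pk["gene_id"] in utr_sum.index:
            cu = utr_sum.loc[pk["gene_id"]].to_numpy(dtype=float)
        else:
            cu = np.zeros_like(ci)
        rows[f"{pk['gene_id']}:{pk['peak_id']}"] = compute_ipui(ci, cu)
    return pd.DataFrame.from_dict(rows, orient="index", columns=counts.columns)


def summarize_cell_ppui(
    cell_matrix: pd.DataFrame,
    units: list[str] | None = None,
) -> pd.Series:
    """Per-cell average pPUI over non-missing units (NaN if none eligible)."""
    mat = cell_matrix if units is None else cell_matrix.loc[units]
    return mat.mean(axis=0, skipna=True)
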