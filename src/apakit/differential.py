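"""Differential PAS usage testing and set operations.

Pearson chi-square (no continuity correction) on peak-count contingency
tables, Benjamini-Hochberg FDR across tested units, shortening vs
lengthening direction calls from the sign of the pPUI difference, trend
tests between adjacent populations, and the Venn/set algebra used to
define mutually dynamic APA sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DiffAPAResult:
    unit_id: str
    comparison: str
    chi2: float
    df: int
    p: float
    q: float = np.nan
    direction: str = "none"


def chi2_counts(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a peaks x columns count table.

    Rows with zero total are dropped (they carry no information and
    would zero the expected counts).  Raises ValueError when any column
    total is zero or fewer than two informative rows remain.
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0]
    if t.shape[0] < 2:
        raise ValueError("need >= 2 peaks with nonzero counts")
    if (t.sum(axis=0) == 0).any():
        raise ValueError("column with zero total")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def chi2_differential(
    unit_counts: dict[str, np.ndarray],
    columns: list[str],
    comparison: str | None = None,
    alpha: float = 0.05,
    ppui: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Chi-square tests across units, with BH correction over all tested.

    ``unit_counts`` maps unit_id -> peaks x len(columns) count table
    (columns ordered as ``columns``).  Units with a zero column total are
    skipped and reported in the second return value.  For pairwise
    comparisons with a ``ppui`` matrix supplied, direction is classified
    via :func:`classify_direction`.
    """
    comparison = comparison or "|".join(columns)
    rows, skipped = [], []
    for unit_id, table in unit_counts.items():
        try:
            chi2, df, p = chi2_counts(np.asarray(table))
        except ValueError:
            skipped.append(unit_id)
            continue
        rows.append(dict(unit_id=unit_id, comparison=comparison,
                         chi2=chi2, df=df, p=p))
    res = pd.DataFrame(rows, columns=["unit_id", "comparison", "chi2", "df", "p"])
    if len(res):
        res["q"] = adjust_bh(res["p"].to_numpy())
    else:
        res["q"] = pd.Series(dtype=float)
    res["direction"] = "none"
    if ppui is not None and len(columns) == 2:
        a, b = columns
        for i, row in res.iterrows():
            res.at[i, "direction"] = classify_direction(
                float(ppui.loc[row["unit_id"], a]),
                float(ppui.loc[row["unit_id"], b]),
                float(row["q"]), alpha,
            )
    return res, skipped


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def classify_direction(ppui_a: float, ppui_b: float, q: float, alpha: float = 0.05) -> str:
    """Direction of APA change in B relative to A.

    Higher pPUI in B at q < alpha -> 3'UTR shortening in B; lower ->
    lengthening; otherwise 'none'.
    """
    if not (q < alpha):
        return "none"
    if ppui_b > ppui_a:
        return "shortening"
    if ppui_b < ppui_a:
        return "lengthening"
    return "none"


def compare_pui_distributions(
    groups: list[np.ndarray],
    method: str = "t",
) -> tuple[float, float]:
    """Two-group (t, ks) or multi-group (kruskal) comparison of index values.

    't' is Welch's two-sided t-test; 'ks' the two-sample
    Kolmogorov-Smirnov test; 'kruskal' the Kruskal-Wallis H test with tie
    correction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if method in ("t", "ks") and len(groups) != 2:
        raise ValueError(f"method {method!r} requires exactly 2 groups")
    if method == "t":
        if any(g.size < 2 for g in groups):
            raise ValueError("t-test requires >= 2 values per group")
        if np.array_equal(groups[0], groups[1]):
            return 0.0, 1.0
        res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    elif method == "ks":
        res = stats.ks_2samp(groups[0], groups[1], method="asymp")
    elif method == "kruskal":
        if len(groups) < 2:
            raise ValueError("kruskal requires >= 2 groups")
        if all(np.array_equal(g, groups[0]) for g in groups[1:]):
            return 0.0, 1.0
        res = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass
class TrendSummary:
    """Adjacent-pair trend along a differentiation ordering."""

    pair: tuple[str, str]
    mean_a: float
    mean_b: float
    t_stat: float
    p: float
    n_shortening: int = 0
    n_lengthening: int = 0


def trend_along_ordering(
    cell_ppui_means: pd.Series,
    cell_clusters: pd.Series,
    ordering: list[str],
    pairwise_direction: dict[tuple[str, str], pd.Series] | None = None,
) -> list[TrendSummary]:
    """Welch t-tests of per-cell average pPUI between adjacent clusters.

    ``cell_ppui_means`` is per-barcode average pPUI; ``cell_clusters``
    maps barcode -> cluster.  When ``pairwise_direction`` supplies the
    per-unit direction calls of the matching comparison, the
    shortening/lengthening tallies are filled.
    """
    out = []
    for a, b in zip(ordering[:-1], ordering[1:]):
        va = cell_ppui_means[cell_clusters == a].dropna().to_numpy()
        vb = cell_ppui_means[cell_clusters == b].dropna().to_numpy()
        t, p = compare_pui_distributions([va, vb], method="t")
        summ = TrendSummary(pair=(a, b), mean_a=float(np.mean(va)),
                            mean_b=float(np.mean(vb)), t_stat=t, p=p)
        if pairwise_direction and (a, b) in pairwise_direction:
            d = pairwise_direction[(a, b)]
            summ.n_shortening = int((d == "shortening").sum())
            summ.n_lengthening = int((d == "lengthening").sum())
        out.append(summ)
    return out


def mutual_dynamic_set(
    set_a: set, set_b: set, set_c: set
) -> tuple[set, dict[str, int]]:
    """A intersect (B union C), plus all seven Venn region sizes."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    mutual = a & (b | c)
    regions = {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB_only": len((a & b) - c),
        "AC_only": len((a & c) - b),
        "BC_only": len((b & c) - a),
        "ABC": len(a & b & c),
    }
    return mutual, regions
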