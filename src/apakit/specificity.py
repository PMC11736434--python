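"""Entropy-based detection of cluster- and stage-specific APA events.

Implements a ROKU-style procedure: subtract a one-step Tukey-biweight
location from each unit's value vector, take absolute values, compute
Shannon entropy, and assign per-column outlier codes via an
AIC-minimizing search over low/high extremes.  Code +1 marks a high
value (specifically shortened 3'UTR for pPUI, enhanced intronic cleavage
for iPUI), -1 a low value, 0 nonspecific.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

BIWEIGHT_C = 5.0
BIWEIGHT_EPS = 1e-4


@dataclass
class ROKUResult:
    unit_id: str
    processed: np.ndarray          # |x - biweight location|
    entropy: float                 # bits
    calls: np.ndarray              # per column in {-1, 0, 1}


def tukey_biweight(x: np.ndarray, c: float = BIWEIGHT_C, eps: float = BIWEIGHT_EPS) -> float:
    """One-step Tukey biweight location estimate.

    u_i = (x_i - median) / (c * MAD + eps); weights (1 - u^2)^2 inside
    |u| < 1 and 0 outside; returns the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    if w.sum() == 0:  # pragma: no cover - median always gets weight
        return float(med)
    return float(np.sum(w * x) / np.sum(w))


def roku_entropy(x: np.ndarray, c: float = BIWEIGHT_C, eps: float = BIWEIGHT_EPS
                 ) -> tuple[np.ndarray, float]:
    """Biweight-centred absolute vector and its Shannon entropy in bits.

    A zero processed vector (constant input) is maximally nonspecific:
    H = log2(n) by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    xp = np.abs(x - tukey_biweight(x, c, eps))
    total = xp.sum()
    if total == 0:
        return xp, float(np.log2(x.size))
    p = xp / total
    nz = p[p > 0]
    return xp, float(-(nz * np.log2(nz)).sum())


def _aic(n: int, s: int, l: int, sigma2: float) -> float:
    if sigma2 <= 0:
        return -math.inf
    return (n - s - l) * math.log(sigma2) + 2 * (s + l + 1)


def roku_call_outliers(x: np.ndarray) -> np.ndarray:
    """AIC-minimizing assignment of {-1, 0, +1} outlier codes.

    For every split (s low-side, l high-side outliers, s + l <= n - 2)
    the AIC of the remaining inliers is (n-s-l) * ln(sigma^2_inlier)
    + 2(s+l+1); the minimizing split labels the s smallest values -1 and
    the l largest +1.  Ties prefer fewer outliers.  A zero-variance
    vector yields all zeros.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 values")
    if np.var(x) == 0:
        return np.zeros(n, dtype=int)
    order = np.argsort(x, kind="mergesort")
    xs = x[order]

    best = (math.inf, 0, 0)
    for total in range(0, n - 1):
        for s in range(total + 1):
            l = total - s
            inliers = xs[s : n - l]
            sigma2 = float(np.var(inliers))
            # -inf AIC (zero inlier variance) still respects the
            # fewer-outliers tie rule because we require strict improvement
            aic = _aic(n, s, l, sigma2)
            if aic < best[0]:
                best = (aic, s, l)
    _, s, l = best
    calls = np.zeros(n, dtype=int)
    calls[order[:s]] = -1
    if l:
        calls[order[n - l:]] = 1
    return calls


def roku(matrix: pd.DataFrame) -> list[ROKUResult]:
    """Run entropy + outlier calling on every row of a unit x column matrix."""
    out = []
    for unit_id, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        xp, h = roku_entropy(x)
        calls = roku_call_outliers(x)
        out.append(ROKUResult(unit_id=unit_id, processed=xp, entropy=h, calls=calls))
    return out


@dataclass
class SpecificEvents:
    """Per-column specific unit sets derived from ROKU calls."""

    high: dict[str, set]      # call == +1 (shortening for pPUI)
    low: dict[str, set]       # call == -1 (lengthening for pPUI)
    ratios: dict[str, float]  # |high| / |low|; inf when low empty; NaN when both empty
    table: pd.DataFrame       # unit x column call codes


def specific_events(matrix: pd.DataFrame,
                    max_entropy: float | None = "auto") -> SpecificEvents:
    """Call per-column specifically high/low units from a complete matrix.

    Outlier codes are only interpreted for low-entropy units: by default
    units with H >= log2(n_columns) - 1 bits are treated as nonspecific
    (entropy ranks specificity; outlier codes alone over-call on pure
    noise).  Pass ``max_entropy=None`` to disable the gate.
    """
    results = roku(matrix)
    if max_entropy == "auto":
        max_entropy = float(np.log2(matrix.shape[1])) - 1.0
    call_rows = []
    for r in results:
        if max_entropy is not None and r.entropy >= max_entropy:
            call_rows.append(np.zeros(matrix.shape[1], dtype=int))
        else:
            call_rows.append(r.calls)
    calls = pd.DataFrame(
        call_rows, index=[r.unit_id for r in results], columns=matrix.columns,
    )
    high = {c: set(calls.index[calls[c] == 1]) for c in calls.columns}
    low = {c: set(calls.index[calls[c] == -1]) for c in calls.columns}
    ratios = {}
    for c in calls.columns:
        nh, nl = len(high[c]), len(low[c])
        if nh == 0 and nl == 0:
            ratios[c] = float("nan")
        elif nl == 0:
            ratios[c] = float("inf")
        else:
            ratios[c] = nh / nl
    return SpecificEvents(high=high, low=low, ratios=ratios, table=calls)


def stage_average(matrix: pd.DataFrame, stage_map: dict[str, str]) -> pd.DataFrame:
    """Average cluster columns into stage columns per a user-supplied map."""
    missing = set(matrix.columns) - set(stage_map)
    if missing:
        raise ValueError(f"clusters without a stage: {sorted(missing)}")
    stages = pd.Series({c: stage_map[c] for c in matrix.columns})
    return matrix.T.groupby(stages).mean().T


def stage_specific_events(matrix: pd.DataFrame, stage_map: dict[str, str]) -> SpecificEvents:
    """ROKU specificity on stage-averaged columns."""
    return specific_events(stage_average(matrix, stage_map))


def pattern_correlation(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of columns plus an average-linkage leaf order.

    Rows with missing values are dropped pairwise for the correlation;
    zero-variance columns yield NA correlations and are excluded from the
    dendrogram.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    corr = matrix.corr(method="pearson")
    usable = [c for c in corr.columns if corr[c].notna().all()]
    if len(usable) >= 2:
        sub = corr.loc[usable, usable]
        dist = squareform((1.0 - sub.to_numpy()).clip(min=0.0), checks=False)
        link = hierarchy.linkage(dist, method="average")
        order = [usable[i] for i in hierarchy.leaves_list(link)]
    else:
        order = usable
    return corr, order


def exhaustive_outlier_oracle(x: np.ndarray) -> np.ndarray:
    """Reference implementation: enumerate every (s, l) split explicitly.

    Kept separate from :func:`roku_call_outliers` as an independent
    cross-check for small n.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if np.var(x) == 0:
        return np.zeros(n, dtype=int)
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    candidates = []
    for s, l in itertools.product(range(n - 1), repeat=2):
        if s + l > n - 2:
            continue
        sigma2 = float(np.var(xs[s : n - l]))
        candidates.append((_aic(n, s, l, sigma2), s + l, s, l))
    candidates.sort(key=lambda t: (t[0], t[1]))
    _, _, s, l = candidates[0]
    calls = np.zeros(n, dtype=int)
    calls[order[:s]] = -1
    if l:
        calls[order[n - l:]] = 1
    return calls
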