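"""Credibility filters and quality control for called PAS peaks.

Implements the CPM-based and internal-priming filters, canonical
poly(A)-signal scanning around peak 3' edges, two-sample comparison of
signal-position densities, and benchmarking against a known-PAS set.

3'UTR peaks are removed when their summed CPM over all clusters is below
10 or when a run of >= 8 adenines starts 10-140 nt downstream of the
peak's 3' edge on the sense strand.  Intronic peaks are removed when any
cluster CPM is below 5, summed CPM is below 10, or a run of >= 7
adenines starts 1-200 nt downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import revcomp

UTR3_RULES = dict(total_cpm_min=10.0, per_cluster_cpm_min=None,
                  a_run=8, a_window=(10, 140))
INTRON_RULES = dict(total_cpm_min=10.0, per_cluster_cpm_min=5.0,
                    a_run=7, a_window=(1, 200))

CANONICAL_MOTIFS = ("AATAAA", "ATTAAA")


@dataclass
class FilterReport:
    """Outcome of :func:`filter_peaks`: survivors plus per-rule removals."""

    surviving: pd.DataFrame
    removed: pd.DataFrame
    removed_by_rule: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.surviving) + len(self.removed)


@dataclass
class MotifProfile:
    """Occurrences of one motif around peak 3' edges.

    ``offsets`` holds, for every occurrence, the offset of the motif's
    last base relative to edge3 (negative = upstream).  ``per_peak``
    maps peak_id -> canonical-signal flag (filled by the caller for the
    canonical motif set).
    """

    motif: str
    window: tuple[int, int]
    offsets: np.ndarray
    per_peak: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    def histogram(self) -> pd.Series:
        vals, counts = np.unique(self.offsets, return_counts=True)
        return pd.Series(counts, index=vals, name=self.motif)

    def mode_offset(self) -> int | None:
        h = self.histogram()
        return None if h.empty else int(h.idxmax())


@dataclass
class BenchmarkResult:
    distances: pd.Series      # per peak_id: signed edge3 - nearest known site
    threshold: int
    fraction_within: float


def _sense_downstream(genome: Mapping[str, str], chrom: str, strand: str,
                      edge3: int, length: int) -> str:
    """Sense-strand sequence covering 1..length nt downstream of edge3."""
    seq = genome[chrom]
    if strand == "+":
        return seq[edge3 + 1 : edge3 + 1 + length]
    lo = max(0, edge3 - length)
    return revcomp(seq[lo:edge3])


def has_a_run(downstream_seq: str, run_length: int, window: tuple[int, int]) -> bool:
    """True if a run of >= run_length 'A' starts within the 1-based window."""
    lo, hi = window
    for m in re.finditer(r"A{%d,}" % run_length, downstream_seq.upper()):
        start_nt = m.start() + 1  # 1-based downstream offset of run start
        if lo <= start_nt <= hi:
            return True
    return False


def filter_peaks(
    peaks: pd.DataFrame,
    cpm: pd.DataFrame,
    genome: Mapping[str, str],
    region_class: str,
    rules: dict | None = None,
) -> FilterReport:
    """Apply the credibility filters for one region class.

    ``peaks`` must carry chrom/strand/edge3 and peak_id; ``cpm`` is the
    peak x cluster CPM view.  A peak is removed iff it violates any
    applicable rule; the report itemizes removals per rule (a peak
    failing two rules counts once in each tally).
    """
    if region_class not in ("utr3", "intron"):
        raise ValueError(f"unknown region_class {region_class!r}")
    if rules is None:
        rules = UTR3_RULES if region_class == "utr3" else INTRON_RULES

    sub = peaks[peaks["region_class"] == region_class]
    tallies = {"low_total_cpm": 0, "low_cluster_cpm": 0, "internal_priming": 0}
    drop = []
    a_len = rules["a_run"]
    win_lo, win_hi = rules["a_window"]
    scan_len = win_hi + a_len  # run must start in window; may extend past it

    for _, pk in sub.iterrows():
        bad = False
        row = cpm.loc[pk["peak_id"]]
        if row.sum() < rules["total_cpm_min"]:
            tallies["low_total_cpm"] += 1
            bad = True
        if rules["per_cluster_cpm_min"] is not None and (row < rules["per_cluster_cpm_min"]).any():
            tallies["low_cluster_cpm"] += 1
            bad = True
        ds = _sense_downstream(genome, pk["chrom"], pk["strand"], int(pk["edge3"]), scan_len)
        if has_a_run(ds, a_len, (win_lo, win_hi)):
            tallies["internal_priming"] += 1
            bad = True
        if bad:
            drop.append(pk["peak_id"])

    dropset = set(drop)
    surviving = sub[~sub["peak_id"].isin(dropset)].reset_index(drop=True)
    removed = sub[sub["peak_id"].isin(dropset)].reset_index(drop=True)
    if rules["per_cluster_cpm_min"] is None:
        del tallies["low_cluster_cpm"]
    return FilterReport(surviving=surviving, removed=removed, removed_by_rule=tallies)


def scan_polya_signals(
    peaks: pd.DataFrame,
    genome: Mapping[str, str],
    upstream: int = 30,
    downstream: int = 150,
    motifs: Sequence[str] = CANONICAL_MOTIFS,
) -> dict[str, MotifProfile]:
    """Scan sense-strand windows around each peak's 3' edge for motifs.

    Every occurrence is recorded as the offset of the motif's last base
    relative to edge3 (negative = upstream).  The per-peak canonical flag
    is any AATAAA/ATTAAA hit inside the window.
    """
    profiles = {m: [] for m in motifs}
    canonical: dict[str, bool] = {}

    for _, pk in peaks.iterrows():
        seq = genome[pk["chrom"]]
        edge3 = int(pk["edge3"])
        if pk["strand"] == "+":
            lo = max(0, edge3 - upstream)
            window_seq = seq[lo : edge3 + 1 + downstream]
            # index i in window_seq has motif-end offset (lo + i) - edge3
            def off(end_i: int) -> int:
                return lo + end_i - edge3
        else:
            lo = max(0, edge3 - downstream)
            hi = min(len(seq), edge3 + 1 + upstream)
            window_seq = revcomp(seq[lo:hi])
            # sense index i maps to genomic hi-1-i; offset = edge3 - genomic
            def off(end_i: int) -> int:
                return edge3 - (hi - 1 - end_i)

        hit_canonical = False
        for motif in motifs:
            for m in re.finditer(f"(?={motif})", window_seq.upper()):
                end_i = m.start() + len(motif) - 1
                o = off(end_i)
                if -upstream <= o <= downstream:
                    profiles[motif].append(o)
                    if motif in CANONICAL_MOTIFS:
                        hit_canonical = True
        canonical[pk["peak_id"]] = hit_canonical

    flag = pd.Series(canonical, dtype=bool)
    return {
        m: MotifProfile(motif=m, window=(-upstream, downstream),
                        offsets=np.asarray(sorted(offs), dtype=int), per_peak=flag)
        for m, offs in profiles.items()
    }


def compare_signal_density(
    offsets_a: np.ndarray,
    offsets_b: np.ndarray,
    window: int = 100,
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on motif offsets within +/-window nt."""
    a = np.asarray(offsets_a)
    b = np.asarray(offsets_b)
    a = a[(a >= -window) & (a <= window)]
    b = b[(b >= -window) & (b <= window)]
    if a.size == 0 or b.size == 0:
        raise ValueError("empty offset sample after windowing")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def benchmark_known_pas(
    peaks: pd.DataFrame,
    known: pd.DataFrame,
    threshold: int = 100,
) -> BenchmarkResult:
    """Distance from each peak 3' edge to the nearest known PAS.

    ``known`` columns: chrom, pos, strand.  Matching is restricted to the
    same chromosome and strand; the signed distance is edge3 - site.
    """
    if known is None or len(known) == 0:
        raise ValueError("known PAS set is empty")
    dists = {}
    grouped = {k: g["pos"].to_numpy() for k, g in known.groupby(["chrom", "strand"])}
    for _, pk in peaks.iterrows():
        sites = grouped.get((pk["chrom"], pk["strand"]))
        if sites is None or sites.size == 0:
            dists[pk["peak_id"]] = np.nan
            continue
        d = int(pk["edge3"]) - sites
        dists[pk["peak_id"]] = d[np.argmin(np.abs(d))]
    ser = pd.Series(dists, name="distance")
    ok = ser.dropna().abs() <= threshold
    frac = float(ok.mean()) if len(ser.dropna()) else 0.0
    return BenchmarkResult(distances=ser, threshold=threshold, fraction_within=frac)
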