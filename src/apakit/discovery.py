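"""PAS peak calling from 3'-tag alignments and count-matrix construction.

The caller is a transparent coverage-run finder: within each annotated
3'UTR or intron interval, maximal runs of positions whose tag-3'-end
coverage reaches ``min_coverage``, with gaps up to ``merge_distance``
closed, become peaks.  The strand-aware downstream-most covered base of a
peak is its 3' edge (the inferred cleavage position).  Each tag is
assigned to at most one peak; 3'UTR intervals take precedence over
introns when a position is covered by both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PEAK_COLUMNS = [
    "peak_id", "gene_id", "region_class", "chrom", "start", "end", "strand", "edge3",
]


@dataclass
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass
class PeakCallResult:
    """Peaks plus the tag->peak assignment and a discard tally."""

    peaks: pd.DataFrame            # PEAK_COLUMNS
    assignments: pd.Series         # index = tag row index, value = peak_id or NA
    n_discarded: int               # tags outside all annotation / unknown chrom


@dataclass
class PeakCountMatrix:
    """Peak x cluster counts with per-cluster library sizes and a CPM view.

    Library size of a cluster is the total tag count carrying that cluster
    label in the input tag set; CPM(p, c) = count(p, c) / library(c) * 1e6.
    """

    counts: pd.DataFrame                      # peaks x clusters, ints
    library_sizes: pd.Series                  # per cluster
    cell_counts: pd.DataFrame | None = None   # long: peak_id, barcode, cluster, count
    cpm: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        lib = self.library_sizes.reindex(self.counts.columns)
        self.cpm = self.counts.div(lib, axis=1) * 1e6


def call_peaks(
    tags: pd.DataFrame,
    annotation: pd.DataFrame,
    min_coverage: int = 5,
    merge_distance: int = 25,
) -> PeakCallResult:
    """Call PAS peaks inside annotated intervals.

    ``tags`` columns: chrom, pos3, strand, barcode, cluster (sorted by
    chrom, pos3).  ``annotation`` columns: chrom, start, end, strand,
    gene_id, region_class, feature_id.
    """
    known_chroms = set(annotation["chrom"])
    bad = ~tags["chrom"].isin(known_chroms)
    if bad.any():
        logger.warning("%d tags on chromosomes absent from annotation; skipped", bad.sum())

    assignment = pd.Series(pd.NA, index=tags.index, dtype="object")
    peak_rows = []
    n_peak = 0

    # utr3 first so shared positions resolve in favour of the 3'UTR
    ordered = pd.concat([
        annotation[annotation["region_class"] == "utr3"],
        annotation[annotation["region_class"] != "utr3"],
    ])

    for _, iv in ordered.iterrows():
        free = assignment.isna()
        in_iv = (
            free
            & (tags["chrom"] == iv["chrom"])
            & (tags["strand"] == iv["strand"])
            & (tags["pos3"] >= iv["start"])
            & (tags["pos3"] < iv["end"])
        )
        idx = tags.index[in_iv]
        if idx.empty:
            continue
        pos = tags.loc[idx, "pos3"].to_numpy()
        rel = pos - iv["start"]
        length = iv["end"] - iv["start"]
        cov = np.bincount(rel, minlength=length)
        covered = np.flatnonzero(cov >= min_coverage)
        if covered.size == 0:
            continue
        # close gaps <= merge_distance between consecutive covered positions
        breaks = np.flatnonzero(np.diff(covered) > merge_distance + 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [covered.size - 1]])
        for rs, re_ in zip(run_starts, run_ends):
            lo = int(covered[rs]) + iv["start"]
            hi = int(covered[re_]) + iv["start"]  # inclusive
            n_peak += 1
            peak_id = f"P{n_peak:05d}"
            edge3 = hi if iv["strand"] == "+" else lo
            peak_rows.append(dict(
                peak_id=peak_id, gene_id=iv["gene_id"],
                region_class=iv["region_class"], chrom=iv["chrom"],
                start=lo, end=hi + 1, strand=iv["strand"], edge3=edge3,
            ))
            member = idx[(pos >= lo) & (pos <= hi)]
            assignment.loc[member] = peak_id

    peaks = pd.DataFrame(peak_rows, columns=PEAK_COLUMNS)
    n_discarded = int(assignment.isna().sum())
    return PeakCallResult(peaks=peaks, assignments=assignment, n_discarded=n_discarded)


def build_count_matrices(
    result: PeakCallResult,
    tags: pd.DataFrame,
    clusters: list[str] | None = None,
    per_cell: bool = False,
) -> tuple[pd.DataFrame, PeakCountMatrix]:
    """Tally assigned tags into a peak x cluster matrix (and per-cell counts).

    Returns the (possibly pruned) peak table and the count matrix; peaks
    spanning zero tags after assignment are dropped with a warning.
    Library sizes are total tag counts per cluster over the full input.
    """
    if clusters is None:
        clusters = sorted(tags["cluster"].unique())
    else:
        missing = [c for c in clusters if c not in set(tags["cluster"])]
        if missing:
            logger.warning("clusters with no tags (zero columns): %s", missing)

    assigned = tags.assign(peak_id=result.assignments).dropna(subset=["peak_id"])
    table = (
        assigned.groupby(["peak_id", "cluster"], observed=True).size().unstack(fill_value=0)
    )
    counts = table.reindex(index=result.peaks["peak_id"], columns=clusters, fill_value=0)
    counts = counts.fillna(0).astype(int)

    empty = counts.sum(axis=1) == 0
    if empty.any():
        logger.warning("dropping %d peaks with zero assigned tags", int(empty.sum()))
    counts = counts.loc[~empty]
    peaks = result.peaks[result.peaks["peak_id"].isin(counts.index)].reset_index(drop=True)

    library = tags.groupby("cluster").size().reindex(clusters, fill_value=0)

    cell_counts = None
    if per_cell:
        cell_counts = (
            assigned.groupby(["peak_id", "barcode", "cluster"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        cell_counts = cell_counts[cell_counts["peak_id"].isin(counts.index)]

    return peaks, PeakCountMatrix(counts=counts, library_sizes=library, cell_counts=cell_counts)
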