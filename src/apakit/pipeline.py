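"""End-to-end orchestration of the APA analysis stages.

``run_pipeline`` wires the stages in dependency order — peak calling,
counting, credibility filtering, index computation, differential testing
and specificity calling — and writes each result as a provenance-headed
TSV.  Reruns with an identical config are bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import differential, discovery, index, io, qc, specificity
from .simulate import SimConfig, generate_reference, simulate_tags


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline; defaults follow the published rules.

    CPM < 10 summed over clusters (3'UTR and intron), CPM < 5 in any
    cluster (intron only), A-run >= 8 at 10-140 nt downstream (3'UTR),
    A-run >= 7 at 1-200 nt (intron), motif window -30/+150 nt, alpha 0.05.
    """

    min_coverage: int = 5
    merge_distance: int = 25
    utr_total_cpm_min: float = 10.0
    intron_total_cpm_min: float = 10.0
    intron_cluster_cpm_min: float = 5.0
    utr_a_run: int = 8
    utr_a_window: tuple[int, int] = (10, 140)
    intron_a_run: int = 7
    intron_a_window: tuple[int, int] = (1, 200)
    motif_upstream: int = 30
    motif_downstream: int = 150
    alpha: float = 0.05
    biweight_c: float = specificity.BIWEIGHT_C
    biweight_eps: float = specificity.BIWEIGHT_EPS
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def utr_rules(self) -> dict:
        return dict(total_cpm_min=self.utr_total_cpm_min, per_cluster_cpm_min=None,
                    a_run=self.utr_a_run, a_window=tuple(self.utr_a_window))

    def intron_rules(self) -> dict:
        return dict(total_cpm_min=self.intron_total_cpm_min,
                    per_cluster_cpm_min=self.intron_cluster_cpm_min,
                    a_run=self.intron_a_run, a_window=tuple(self.intron_a_window))


@dataclass
class PipelineResult:
    peaks: pd.DataFrame
    counts: discovery.PeakCountMatrix
    utr_filter: qc.FilterReport
    intron_filter: qc.FilterReport
    ppui: pd.DataFrame
    ipui: pd.DataFrame
    omnibus: pd.DataFrame
    pairwise: dict[tuple[str, str], pd.DataFrame]
    specific: specificity.SpecificEvents | None
    extras: dict[str, Any] = field(default_factory=dict)


def run_pipeline(
    tags: pd.DataFrame,
    annotation: pd.DataFrame,
    genome: dict[str, str],
    cluster_ordering: list[str],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every analysis stage on one tag set; optionally write TSVs."""
    cfg = config or PipelineConfig()

    called = discovery.call_peaks(tags, annotation, cfg.min_coverage, cfg.merge_distance)
    peaks, counts = discovery.build_count_matrices(
        called, tags, clusters=cluster_ordering, per_cell=True
    )

    utr_report = qc.filter_peaks(peaks, counts.cpm, genome, "utr3", rules=cfg.utr_rules())
    intron_report = qc.filter_peaks(peaks, counts.cpm, genome, "intron",
                                    rules=cfg.intron_rules())
    kept = pd.concat([utr_report.surviving, intron_report.surviving], ignore_index=True)

    groups, n_single = index.group_utr_peaks(kept)
    ppui = index.compute_ppui(groups, counts.counts)
    ipui = index.compute_ipui_matrix(kept, counts.counts)

    unit_tables = {
        g.utr_id: counts.counts.loc[g.peak_ids, cluster_ordering].to_numpy()
        for g in groups
    }
    omnibus, skipped = differential.chi2_differential(
        unit_tables, cluster_ordering, comparison="omnibus", alpha=cfg.alpha
    )
    pairwise = {}
    for a, b in zip(cluster_ordering[:-1], cluster_ordering[1:]):
        tabs = {g.utr_id: counts.counts.loc[g.peak_ids, [a, b]].to_numpy() for g in groups}
        res, _ = differential.chi2_differential(tabs, [a, b], alpha=cfg.alpha, ppui=ppui)
        pairwise[(a, b)] = res

    # outlier search needs >= 3 columns (s + l <= n - 2)
    spec = (specificity.specific_events(ppui)
            if len(ppui) and ppui.shape[1] >= 3 else None)

    result = PipelineResult(
        peaks=peaks, counts=counts, utr_filter=utr_report,
        intron_filter=intron_report, ppui=ppui, ipui=ipui,
        omnibus=omnibus, pairwise=pairwise, specific=spec,
        extras=dict(n_single_pas_utrs=n_single, skipped_units=skipped,
                    n_discarded_tags=called.n_discarded),
    )
    if outdir is not None:
        write_pipeline_outputs(result, cfg, Path(outdir))
    return result


def write_pipeline_outputs(result: PipelineResult, cfg: PipelineConfig,
                           outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = io.provenance_header(cfg.to_dict(), seed=cfg.seed)
    io.write_tsv(result.peaks, outdir / "peaks.tsv", header, index=False)
    io.write_tsv(result.counts.counts, outdir / "peak_counts.tsv", header)
    io.write_tsv(result.counts.cpm, outdir / "peak_cpm.tsv", header)
    io.write_tsv(result.ppui, outdir / "ppui_clusters.tsv", header)
    io.write_tsv(result.ipui, outdir / "ipui_clusters.tsv", header)
    io.write_tsv(result.omnibus, outdir / "diff_omnibus.tsv", header, index=False)
    for (a, b), res in result.pairwise.items():
        io.write_tsv(res, outdir / f"diff_{a}_vs_{b}.tsv", header, index=False)
    if result.specific is not None:
        io.write_tsv(result.specific.table, outdir / "specific_calls.tsv", header)
        ratios = pd.DataFrame({"ratio": pd.Series(result.specific.ratios)})
        io.write_tsv(ratios, outdir / "specific_ratios.tsv", header)


def simulate_bundle(sim_config: SimConfig, outdir: str | Path | None = None):
    """Generate reference + tags, optionally writing FASTA/BED/TSV files."""
    genome, annotation, truth = generate_reference(sim_config)
    tags = simulate_tags(genome, annotation, truth, sim_config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = io.provenance_header(sim_config.to_dict(), seed=sim_config.seed)
        io.write_fasta(genome, outdir / "genome.fa")
        io.write_annotation_bed(annotation, outdir / "annotation.bed")
        io.write_tags_bed(tags, outdir / "tags.bed")
        io.write_tsv(truth.genes, outdir / "truth_genes.tsv", header, index=False)
        io.write_tsv(truth.sites, outdir / "truth_sites.tsv", header, index=False)
        io.write_tsv(truth.usage, outdir / "truth_usage.tsv", header, index=False)
    return genome, annotation, truth, tags
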