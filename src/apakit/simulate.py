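"""Synthetic 3'-tag data with known polyadenylation-site ground truth.

Generates a toy genome (FASTA-able), a gene annotation with 3'UTR and intron
intervals, a truth table of per-cluster PAS usage proportions, and per-cell
3'-tag records.  Every planted feature downstream code must detect — AATAAA
signals upstream of cleavage sites, A-rich internal-priming artifacts,
monotone proximal-usage shifts along a differentiation ordering — is
recorded in the truth table so tests can score recovery exactly.

Coordinates are 0-based half-open throughout; ``pos3`` is the 0-based
coordinate of a tag's 3'-most aligned base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_SIGNAL = "AATAAA"

# gene body layout (relative, plus-strand orientation, before mirroring)
_EXON1_LEN = 100
_INTRON_LEN = 400
_EXON2_LEN = 100
_INTERGENIC = 300

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Knobs for the synthetic data generator.

    All fractions live in [0, 1]; ``seed`` fully determines every output.
    ``pas_per_utr`` is a distribution over {1, 2, 3} 3'UTR PASs per gene.
    ``shift_delta`` is the total proximal-usage increase applied linearly
    along ``cluster_ordering`` to genes flagged as shifted.
    """

    n_genes: int = 60
    n_clusters: int = 4
    cluster_ordering: Sequence[str] | None = None
    cells_per_cluster: int = 50
    mean_tags_per_cell_per_gene: float = 2.0
    pas_per_utr: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.5, 3: 0.3}
    )
    frac_shift_genes: float = 0.3
    shift_delta: float = 0.3
    base_proximal_usage: float = 0.3
    intron_pas_prob: float = 0.2
    intron_usage_frac: float = 0.15
    artifact_rate: float = 0.1
    signal_offset: int = 21
    jitter_sd: float = 5.0
    utr_pas_spacing: int = 150
    utr_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_ordering is None:
            self.cluster_ordering = [f"C{i + 1}" for i in range(self.n_clusters)]
        self.cluster_ordering = list(self.cluster_ordering)
        if len(self.cluster_ordering) != self.n_clusters:
            raise ValueError("cluster_ordering length must equal n_clusters")
        for name, frac in [
            ("frac_shift_genes", self.frac_shift_genes),
            ("intron_pas_prob", self.intron_pas_prob),
            ("artifact_rate", self.artifact_rate),
            ("intron_usage_frac", self.intron_usage_frac),
            ("base_proximal_usage", self.base_proximal_usage),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if self.base_proximal_usage + self.shift_delta > 1.0 + 1e-12:
            raise ValueError("base_proximal_usage + shift_delta must be <= 1")
        if abs(sum(self.pas_per_utr.values()) - 1.0) > 1e-9:
            raise ValueError("pas_per_utr probabilities must sum to 1")
        if any(k not in (1, 2, 3) for k in self.pas_per_utr):
            raise ValueError("pas_per_utr keys must be in {1, 2, 3}")
        if self.mean_tags_per_cell_per_gene <= 0:
            raise ValueError("mean_tags_per_cell_per_gene must be positive")
        max_pas = max(k for k, v in self.pas_per_utr.items() if v > 0)
        if self.utr_length is not None:
            needed = self._utr_len(max_pas)
            if self.utr_length < needed:
                raise ValueError(
                    f"utr_length={self.utr_length} cannot hold {max_pas} PASs "
                    f"spaced {self.utr_pas_spacing} nt (need >= {needed})"
                )

    def _utr_len(self, n_pas: int) -> int:
        # 100 nt lead-in, spacing between sites, 450 nt tail (artifact room)
        return 100 + self.utr_pas_spacing * n_pas + 350

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pas_per_utr"] = {str(k): v for k, v in dict(self.pas_per_utr).items()}
        return d


@dataclass
class TruthTable:
    """Ground truth emitted by :func:`generate_reference`.

    genes : per-gene flags (shifted/stable, artifact, intronic PAS)
    sites : every planted site with kind in {utr3, intron, artifact};
            ``rank`` orders 3'UTR sites proximal(1) -> distal
    usage : per gene x cluster x true-site usage proportion (sums to 1)
    """

    genes: pd.DataFrame
    sites: pd.DataFrame
    usage: pd.DataFrame

    def usage_matrix(self, gene_id: str) -> pd.DataFrame:
        """Site x cluster proportion table for one gene."""
        sub = self.usage[self.usage["gene_id"] == gene_id]
        return sub.pivot(index="site_id", columns="cluster", values="proportion")


def _break_runs(arr: np.ndarray, letter: bytes, max_run: int = 5) -> None:
    """Cap homopolymer runs of ``letter`` at ``max_run`` in place."""
    mask = arr == letter[0]
    run = 0
    for i in range(arr.size):
        if mask[i]:
            run += 1
            if run > max_run:
                arr[i] = ord("C") if letter != b"C" else ord("G")
                run = 0
        else:
            run = 0


def _plant_sense_motif(chrom: np.ndarray, strand: str, end_pos: int, motif: str) -> None:
    """Write ``motif`` on the sense strand so its last base sits at ``end_pos``."""
    if strand == "+":
        start = end_pos - len(motif) + 1
        chrom[start : end_pos + 1] = np.frombuffer(motif.encode(), dtype=np.uint8)
    else:
        rc = revcomp(motif)
        chrom[end_pos : end_pos + len(motif)] = np.frombuffer(rc.encode(), dtype=np.uint8)


def _plant_guarded_signal(chrom: np.ndarray, strand: str, end_pos: int, motif: str) -> None:
    """Plant a signal flanked by CG guards so no accidental A/T run forms."""
    guard = "CGCGC"
    if strand == "+":
        _plant_sense_motif(chrom, strand, end_pos - len(motif), guard)  # upstream
        _plant_sense_motif(chrom, strand, end_pos + len(guard), guard)  # downstream
    else:
        _plant_sense_motif(chrom, strand, end_pos + len(motif), guard)
        _plant_sense_motif(chrom, strand, end_pos - len(guard), guard)
    _plant_sense_motif(chrom, strand, end_pos, motif)


def _plant_sense_a_run(chrom: np.ndarray, strand: str, site: int, offset: int, length: int) -> None:
    """Plant ``length`` sense-strand adenines starting ``offset`` nt downstream of ``site``."""
    if strand == "+":
        chrom[site + offset : site + offset + length] = ord("A")
    else:
        chrom[site - offset - length + 1 : site - offset + 1] = ord("T")


def generate_reference(
    config: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame, TruthTable]:
    """Build genome, annotation and truth table from ``config``.

    Returns
    -------
    genome : dict of chrom name -> sequence string
    annotation : DataFrame(chrom, start, end, strand, gene_id, region_class,
        feature_id) with 0-based half-open intervals
    truth : :class:`TruthTable`
    """
    rng = np.random.default_rng([config.seed, 0])
    clusters = list(config.cluster_ordering)
    n_k = len(clusters)

    pas_keys = np.array(sorted(config.pas_per_utr))
    pas_probs = np.array([config.pas_per_utr[k] for k in pas_keys], dtype=float)
    n_pas_per_gene = rng.choice(pas_keys, size=config.n_genes, p=pas_probs)

    multi = np.flatnonzero(n_pas_per_gene >= 2)
    n_shift = int(round(config.frac_shift_genes * multi.size))
    shifted_idx = set(rng.choice(multi, size=n_shift, replace=False).tolist()) if n_shift else set()
    has_intron_pas = rng.random(config.n_genes) < config.intron_pas_prob
    has_artifact = rng.random(config.n_genes) < config.artifact_rate

    spacing = config.utr_pas_spacing
    gene_rows, site_rows, usage_rows, ann_rows = [], [], [], []
    seq_parts: list[np.ndarray] = []
    cursor = 0

    for gi in range(config.n_genes):
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_pas = int(n_pas_per_gene[gi])
        utr_len = config.utr_length if config.utr_length is not None else config._utr_len(n_pas)
        gene_len = _EXON1_LEN + _INTRON_LEN + _EXON2_LEN + utr_len

        body = rng.integers(0, 4, size=gene_len + _INTERGENIC)
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)[body].copy()
        _break_runs(arr, b"A")
        _break_runs(arr, b"T")

        g0 = cursor  # absolute gene start on the single chromosome

        # relative plus-orientation layout, mirrored below for minus genes
        def absolute(rel: int) -> int:
            if strand == "+":
                return g0 + rel
            return g0 + gene_len - 1 - rel

        def interval(rel_start: int, rel_end: int) -> tuple[int, int]:
            if strand == "+":
                return g0 + rel_start, g0 + rel_end
            return g0 + gene_len - rel_end, g0 + gene_len - rel_start

        intron_rel = (_EXON1_LEN, _EXON1_LEN + _INTRON_LEN)
        utr_rel = (gene_len - utr_len, gene_len)

        for (rs, re), klass in [(intron_rel, "intron"), (utr_rel, "utr3")]:
            s, e = interval(rs, re)
            ann_rows.append(
                dict(chrom="chr1", start=s, end=e, strand=strand,
                     gene_id=gene_id, region_class=klass,
                     feature_id=f"{gene_id}:{klass}")
            )

        utr_sites = []
        for r in range(n_pas):
            site = absolute(utr_rel[0] + 100 + spacing * r)
            sid = f"{gene_id}:utr3:{r + 1}"
            utr_sites.append(sid)
            site_rows.append(dict(gene_id=gene_id, site_id=sid, kind="utr3",
                                  chrom="chr1", strand=strand, pos3=site, rank=r + 1))

        intron_site_id = None
        if has_intron_pas[gi]:
            site = absolute(intron_rel[0] + 200)
            intron_site_id = f"{gene_id}:intron:1"
            site_rows.append(dict(gene_id=gene_id, site_id=intron_site_id, kind="intron",
                                  chrom="chr1", strand=strand, pos3=site, rank=0))

        artifact_site = None
        if has_artifact[gi]:
            rel = utr_rel[0] + 100 + spacing * n_pas + 150
            artifact_site = absolute(rel)
            site_rows.append(dict(gene_id=gene_id, site_id=f"{gene_id}:artifact:1",
                                  kind="artifact", chrom="chr1", strand=strand,
                                  pos3=artifact_site, rank=0))

        shifted = gi in shifted_idx
        gene_rows.append(dict(gene_id=gene_id, chrom="chr1", strand=strand,
                              n_utr_pas=n_pas, shifted=shifted,
                              has_intron_pas=bool(has_intron_pas[gi]),
                              has_artifact=bool(has_artifact[gi])))

        # usage proportions per cluster over true sites (artifact excluded)
        if n_pas >= 2:
            other_w = rng.dirichlet(np.full(n_pas - 1, 5.0))
        else:
            other_w = np.array([])
        for j, cl in enumerate(clusters):
            if n_pas == 1:
                utr_props = np.array([1.0])
            else:
                frac = j / (n_k - 1) if n_k > 1 else 0.0
                prox = config.base_proximal_usage + (config.shift_delta * frac if shifted else 0.0)
                utr_props = np.concatenate([[prox], (1.0 - prox) * other_w])
            if intron_site_id is not None:
                props = np.concatenate(
                    [utr_props * (1.0 - config.intron_usage_frac), [config.intron_usage_frac]]
                )
                ids = utr_sites + [intron_site_id]
            else:
                props, ids = utr_props, utr_sites
            for sid, p in zip(ids, props):
                usage_rows.append(dict(gene_id=gene_id, site_id=sid, cluster=cl, proportion=p))

        seq_parts.append(arr)
        cursor += arr.size

    chrom = np.concatenate(seq_parts)
    sites = pd.DataFrame(site_rows)
    for _, row in sites.iterrows():
        if row["kind"] == "artifact":
            # offset 40 keeps the run start inside the 10-140 nt filter
            # window even after peak-edge jitter of ~15 nt
            _plant_sense_a_run(chrom, row["strand"], int(row["pos3"]), offset=40, length=12)
        else:
            end = (int(row["pos3"]) - config.signal_offset if row["strand"] == "+"
                   else int(row["pos3"]) + config.signal_offset)
            _plant_guarded_signal(chrom, row["strand"], end, CANONICAL_SIGNAL)

    genome = {"chr1": chrom.tobytes().decode("ascii")}
    annotation = pd.DataFrame(ann_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        sites=sites,
        usage=pd.DataFrame(usage_rows),
    )
    return genome, annotation, truth


def simulate_tags(
    genome: Mapping[str, str],
    annotation: pd.DataFrame,
    truth: TruthTable,
    config: SimConfig,
) -> pd.DataFrame:
    """Draw per-cell 3'-tags from the truth proportions.

    For every cell x gene the tag count is Poisson with mean
    ``mean_tags_per_cell_per_gene``; each tag picks a true site by the
    gene x cluster usage proportions and lands at the cleavage site plus
    rounded Gaussian jitter.  Genes flagged with an artifact additionally
    emit Poisson-distributed tags at the artifact locus.

    Returns a DataFrame(chrom, pos3, strand, barcode, cluster) sorted by
    (chrom, pos3), writable as BED6 with name = "barcode:cluster".
    """
    if annotation is None or len(annotation) == 0:
        raise ValueError("annotation is empty")
    rng = np.random.default_rng([config.seed, 1])
    clusters = list(config.cluster_ordering)
    chrom_len = {c: len(s) for c, s in genome.items()}

    site_pos = truth.sites.set_index("site_id")["pos3"].to_dict()
    site_chrom = truth.sites.set_index("site_id")["chrom"].to_dict()
    site_strand = truth.sites.set_index("site_id")["strand"].to_dict()
    artifact_by_gene = {
        r["gene_id"]: r["site_id"]
        for _, r in truth.sites[truth.sites["kind"] == "artifact"].iterrows()
    }

    usage = truth.usage
    out_chrom, out_pos, out_strand, out_bc, out_cl = [], [], [], [], []

    def emit(site_id: str, n: int, barcodes: np.ndarray, cluster: str) -> None:
        if n == 0:
            return
        pos = np.full(n, site_pos[site_id], dtype=np.int64)
        if config.jitter_sd > 0:
            pos = pos + np.rint(rng.normal(0.0, config.jitter_sd, size=n)).astype(np.int64)
        cname = site_chrom[site_id]
        pos = np.clip(pos, 0, chrom_len[cname] - 1)
        out_chrom.append(np.full(n, cname, dtype=object))
        out_pos.append(pos)
        out_strand.append(np.full(n, site_strand[site_id], dtype=object))
        out_bc.append(barcodes)
        out_cl.append(np.full(n, cluster, dtype=object))

    for _, gene in truth.genes.iterrows():
        gene_id = gene["gene_id"]
        gusage = usage[usage["gene_id"] == gene_id]
        for cluster in clusters:
            cu = gusage[gusage["cluster"] == cluster]
            ids = cu["site_id"].to_numpy()
            props = cu["proportion"].to_numpy(dtype=float)
            cell_counts = rng.poisson(config.mean_tags_per_cell_per_gene,
                                      size=config.cells_per_cluster)
            total = int(cell_counts.sum())
            barcodes = np.repeat(
                np.array([f"{cluster}_cell{j + 1}" for j in range(config.cells_per_cluster)],
                         dtype=object),
                cell_counts,
            )
            if total:
                choice = rng.choice(ids.size, size=total, p=props)
                for k, sid in enumerate(ids):
                    sel = choice == k
                    emit(sid, int(sel.sum()), barcodes[sel], cluster)
            if gene["has_artifact"]:
                # artifact loci pile up at the gene's own expression rate so
                # they form genuine peaks the QC filters must remove
                art_counts = rng.poisson(config.mean_tags_per_cell_per_gene,
                                         size=config.cells_per_cluster)
                a_bc = np.repeat(
                    np.array([f"{cluster}_cell{j + 1}"
                              for j in range(config.cells_per_cluster)], dtype=object),
                    art_counts,
                )
                emit(artifact_by_gene[gene_id], int(art_counts.sum()), a_bc, cluster)

    if not out_pos:
        tags = pd.DataFrame(columns=["chrom", "pos3", "strand", "barcode", "cluster"])
    else:
        tags = pd.DataFrame(
            {
                "chrom": np.concatenate(out_chrom),
                "pos3": np.concatenate(out_pos),
                "strand": np.concatenate(out_strand),
                "barcode": np.concatenate(out_bc),
                "cluster": np.concatenate(out_cl),
            }
        )
    tags = tags.sort_values(["chrom", "pos3"], kind="mergesort").reset_index(drop=True)
    tags["pos3"] = tags["pos3"].astype(np.int64)
    return tags
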