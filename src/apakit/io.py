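"""Format adapters: FASTA, BED6, GTF and TSV with provenance headers.

Internal coordinates are 0-based half-open.  BED is written/read as-is
(0-based); GTF is 1-based inclusive and converted on input.  Tag BED6
records carry "barcode:cluster" in the name field.  All TSV outputs use
the missing-value token "NA" and may start with '#' provenance lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NA_TOKEN = "NA"

TAG_COLUMNS = ["chrom", "pos3", "strand", "barcode", "cluster"]
ANNOTATION_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "region_class", "feature_id"]


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tags_bed(tags: pd.DataFrame, path: str | Path) -> None:
    """Tags as BED6: chrom, pos3, pos3+1, barcode:cluster, 0, strand."""
    bed = pd.DataFrame({
        "chrom": tags["chrom"],
        "start": tags["pos3"],
        "end": tags["pos3"] + 1,
        "name": tags["barcode"].astype(str) + ":" + tags["cluster"].astype(str),
        "score": 0,
        "strand": tags["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tags_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "name", "score", "strand"])
    name = bed["name"].astype(str)
    barcode = name.str.rsplit(":", n=1).str[0]
    cluster = name.str.rsplit(":", n=1).str[1]
    tags = pd.DataFrame({
        "chrom": bed["chrom"], "pos3": bed["start"].astype(int),
        "strand": bed["strand"], "barcode": barcode, "cluster": cluster,
    })
    return tags.sort_values(["chrom", "pos3"], kind="mergesort").reset_index(drop=True)


def write_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Annotation as BED6 with name = gene_id|region_class|feature_id."""
    bed = pd.DataFrame({
        "chrom": annotation["chrom"],
        "start": annotation["start"],
        "end": annotation["end"],
        "name": (annotation["gene_id"].astype(str) + "|"
                 + annotation["region_class"].astype(str) + "|"
                 + annotation["feature_id"].astype(str)),
        "score": 0,
        "strand": annotation["strand"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "start", "end", "name", "score", "strand"])
    parts = bed["name"].astype(str).str.split("|", expand=True)
    if parts.shape[1] < 3:
        raise ValueError("annotation BED name must be gene_id|region_class|feature_id")
    ann = pd.DataFrame({
        "chrom": bed["chrom"], "start": bed["start"].astype(int),
        "end": bed["end"].astype(int), "strand": bed["strand"],
        "gene_id": parts[0], "region_class": parts[1], "feature_id": parts[2],
    })
    return ann[ANNOTATION_COLUMNS]


def read_annotation_gtf(path: str | Path,
                        utr_feature: str = "three_prime_utr",
                        intron_feature: str = "intron") -> pd.DataFrame:
    """Minimal GTF ingestion: keeps 3'UTR and intron features.

    GTF is 1-based inclusive; converted to 0-based half-open on input.
    The gene_id attribute is required.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            feature = f[2]
            if feature not in (utr_feature, intron_feature):
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].strip().rstrip(";").split(";")
                if kv.strip()
            )
            gene_id = attrs.get("gene_id", "").strip('"')
            if not gene_id:
                raise ValueError(f"GTF record without gene_id: {line!r}")
            region = "utr3" if feature == utr_feature else "intron"
            rows.append(dict(
                chrom=f[0], start=int(f[3]) - 1, end=int(f[4]), strand=f[6],
                gene_id=gene_id, region_class=region,
                feature_id=f"{gene_id}:{region}",
            ))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_known_pas_bed(path: str | Path) -> pd.DataFrame:
    """Known PAS sites from BED: position = start, strand from column 6 or '+'."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    strand = bed[5] if bed.shape[1] >= 6 else "+"
    return pd.DataFrame({"chrom": bed[0], "pos": bed[1].astype(int), "strand": strand})


def provenance_header(config: dict, seed: int | None = None, version: str = "") -> str:
    blob = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    parts = [f"# apakit{(' ' + version) if version else ''}",
             f"# config-hash={digest}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    return "\n".join(parts) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, header: str | None = None,
              index: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", na_rep=NA_TOKEN, index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col,
                       na_values=[NA_TOKEN], keep_default_na=True)
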