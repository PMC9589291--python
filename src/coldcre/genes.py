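"""Gene records: three strand-relative regions plus GO annotations.

Each gene carries the sequence of its 1 kb upstream flank, its gene body
(including UTRs) and its 1 kb downstream flank, all written 5'->3' on the
gene's own strand (upstream is always 5' of the gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGIONS = ("upstream", "body", "downstream")


@dataclass
class GeneRecord:
    gene_id: str
    upstream_seq: str = ""
    body_seq: str = ""
    downstream_seq: str = ""
    strand: str = "+"
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.upstream_seq = self.upstream_seq.upper()
        self.body_seq = self.body_seq.upper()
        self.downstream_seq = self.downstream_seq.upper()
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def region(self, name: str) -> str:
        return getattr(self, f"{name}_seq")

    def regions(self) -> dict[str, str]:
        return {r: self.region(r) for r in REGIONS}


def write_region_fasta(genes: list[GeneRecord], path) -> None:
    """Multi-FASTA with one record per gene region, headers ``gene_id|region``."""
    records = [
        SeqRecord(Seq(g.region(r)), id=f"{g.gene_id}|{r}", description="")
        for g in genes
        for r in REGIONS
    ]
    SeqIO.write(records, str(path), "fasta")


def read_region_fasta(path) -> list[GeneRecord]:
    by_gene: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, _, region = rec.id.partition("|")
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r} in FASTA header {rec.id!r}")
        if gene_id not in by_gene:
            by_gene[gene_id] = {}
            order.append(gene_id)
        by_gene[gene_id][region] = str(rec.seq).upper()
    return [
        GeneRecord(
            gene_id=g,
            upstream_seq=by_gene[g].get("upstream", ""),
            body_seq=by_gene[g].get("body", ""),
            downstream_seq=by_gene[g].get("downstream", ""),
        )
        for g in order
    ]


def extract_regions(
    genome_fasta, gff3_path, flank: int = 1000
) -> list[GeneRecord]:
    """Extract per-gene regions from a genome FASTA + GFF3 annotation.

    GFF3 coordinates are 1-based inclusive.  For minus-strand genes every
    region is reverse-complemented and upstream/downstream are swapped so
    that regions are strand-relative.  Flanks are truncated at contig ends.
    """
    import gffutils

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", keep_order=True,
                            merge_strategy="create_unique")
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        seq = contigs[feat.seqid]
        start, end = feat.start, feat.end  # 1-based inclusive
        left = seq[max(0, start - 1 - flank): start - 1]
        body = seq[start - 1: end]
        right = seq[end: end + flank]
        if feat.strand == "-":
            left, right = _rc(right), _rc(left)
            body = _rc(body)
        genes.append(
            GeneRecord(gene_id=feat.id, upstream_seq=left, body_seq=body,
                       downstream_seq=right, strand=feat.strand or "+")
        )
    return genes


def _rc(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def write_go_tsv(genes: list[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for g in genes:
            for term in sorted(g.go_terms):
                fh.write(f"{g.gene_id}\t{term}\n")


def read_go_tsv(path) -> dict[str, set[str]]:
    import csv

    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["gene_id"], set()).add(row["term_id"])
    return out
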