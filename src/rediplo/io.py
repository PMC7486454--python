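"""Readers and writers for the on-disk formats the pipeline exchanges.

Internal coordinates are 0-based half-open everywhere; conversion to/from
1-based happens only at the GFF3 and VCF boundaries.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with a single contiguous CDS.

    ``start``/``end`` are 0-based half-open genomic coordinates of the gene
    body (UTRs included); ``cds_start``/``cds_end`` delimit the coding
    region within it (defaulting to the full body).  ``strand`` is '+' or
    '-'.  The coding sequence read 5'→3' on the coding strand is
    ``cds(sequences)``.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    cds_start: int = -1
    cds_end: int = -1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.cds_start < 0:
            object.__setattr__(self, "cds_start", self.start)
            object.__setattr__(self, "cds_end", self.end)
        if not (self.start <= self.cds_start < self.cds_end <= self.end):
            raise ValueError(f"{self.gene_id}: CDS outside gene body")

    @property
    def length(self) -> int:
        return self.end - self.start

    def cds(self, sequences: dict[str, str]) -> str:
        seg = sequences[self.contig][self.cds_start:self.cds_end]
        if self.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        return seg


# --------------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------- GFF3

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            start1, end1 = g.start + 1, g.end  # 1-based inclusive
            fh.write(
                f"{g.contig}\trediplo\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.contig}\trediplo\tmRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.contig}\trediplo\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3; multi-segment CDS are collapsed to their
    genomic span (the pipeline's simulator emits single-CDS genes)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds = list(db.children(g, featuretype="CDS"))
        if cds:
            cds_start = min(c.start for c in cds) - 1
            cds_end = max(c.end for c in cds)
        else:
            cds_start, cds_end = g.start - 1, g.end
        genes.append(
            GeneModel(
                gene_id=g.id,
                contig=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes


# ------------------------------------------------------- TE annotation table

TE_COLUMNS = ["contig", "start", "end", "family", "score", "strand",
              "te_class", "pct_divergence"]


def write_te_table(te: pd.DataFrame, path: str | Path) -> None:
    """BED6+2: contig, start, end, family, score, strand, class, %divergence.
    Coordinates 0-based half-open."""
    out = te.copy()
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "+"
    out[TE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_te_table(path: str | Path) -> pd.DataFrame:
    te = pd.read_csv(path, sep="\t", header=None, names=TE_COLUMNS)
    return te


# ----------------------------------------------------------------------- VCF

def write_vcf(snps: pd.DataFrame, contig_lengths: dict[str, int],
              path: str | Path) -> None:
    """Write a sites-only VCF v4.2.  ``snps`` has columns contig, pos
    (0-based), ref, alt; positions are converted to 1-based on output."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rediplo\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        snps = snps.sort_values(["contig", "pos"])
        for row in snps.itertuples(index=False):
            fh.write(f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read SNP sites from a VCF into a frame with 0-based positions."""
    from cyvcf2 import VCF

    rows = []
    for var in VCF(str(path)):
        rows.append((var.CHROM, var.POS - 1, var.REF,
                     var.ALT[0] if var.ALT else "."))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])


# ---------------------------------------------------------------- expression

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    """Gene × tissue FPKM matrix, index name gene_id."""
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
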