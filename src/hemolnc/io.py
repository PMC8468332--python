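"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython, GFF3 via gffutils (1-based closed on disk,
converted to 0-based half-open in memory), BED6 (0-based half-open),
minimal SAM via pysam, and plain TSV tables via pandas.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_context import GeneAnnotation, GenomePlacement


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- homology hits (12-column tabular) --------------------------------------

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path) -> pd.DataFrame:
    """Read 12-column tabular homology output, erroring with the line
    number on rows with the wrong arity."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 12 columns, found {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    if len(df):
        df["evalue"] = pd.to_numeric(df["evalue"])
        df["bitscore"] = pd.to_numeric(df["bitscore"])
    return df


def write_blast_tabular(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# -- GFF3 -------------------------------------------------------------------

def read_gff3_genes(path) -> list[GeneAnnotation]:
    """Gene records from GFF3; coordinates converted to 0-based half-open."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        go = feat.attributes.get("Ontology_term", [])
        genes.append(
            GeneAnnotation(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based closed
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                go_terms=tuple(go),
            )
        )
    return genes


def write_gff3_genes(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.go_terms:
                attrs += ";Ontology_term=" + ",".join(g.go_terms)
            fh.write(
                f"{g.chrom}\themolnc\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# -- BED6 -------------------------------------------------------------------

def read_bed_placements(path) -> list[GenomePlacement]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        GenomePlacement(row.name, row.chrom, int(row.start), int(row.end), row.strand)
        for row in df.itertuples(index=False)
    ]


def write_bed_placements(placements: list[GenomePlacement], path) -> None:
    with open(path, "w") as fh:
        for p in placements:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.transcript_id}\t0\t{p.strand}\n")


# -- minimal SAM ------------------------------------------------------------

def read_sam_placements(path, chrom_lengths: dict[str, int] | None = None) -> list[GenomePlacement]:
    """Placements from a minimal text SAM (QNAME/FLAG/RNAME/POS/CIGAR).

    Alignment span on the reference is taken from the CIGAR; unmapped
    records (FLAG 0x4 or RNAME "*") are skipped. An RNAME absent from
    ``chrom_lengths`` (when given) is an error.
    """
    import pysam

    placements = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name is None:
                continue
            chrom = aln.reference_name
            if chrom_lengths is not None and chrom not in chrom_lengths:
                raise ValueError(f"alignment references unknown chromosome {chrom!r}")
            placements.append(
                GenomePlacement(
                    aln.query_name,
                    chrom,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                )
            )
    return placements


# -- TSV tables -------------------------------------------------------------

def read_coverage_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]].astype(float)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene2go_tsv(path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(gene, set()).add(term)
    return out


def write_gene2go_tsv(gene2go: dict[str, set[str]], path) -> None:
    rows = [
        {"gene_id": g, "go_id": t}
        for g in sorted(gene2go)
        for t in sorted(gene2go[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "go_id"]).to_csv(path, sep="\t", index=False)
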