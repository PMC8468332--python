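"""Genome placement of putative lncRNAs and cis-neighbor extraction.

A placed lncRNA is linked to every protein-coding gene lying within a
fixed window (default 10 kb, boundary inclusive) upstream or downstream
of its locus, strand-agnostically. All internal coordinates are 0-based
half-open; conversions to GFF3 (1-based closed) and BED happen only at
file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from intervaltree import IntervalTree

from .orf import reverse_complement

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomePlacement:
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.transcript_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open internally
    end: int
    strand: str = "+"
    go_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid interval")
        for t in self.go_terms:
            if not (t.startswith("GO:") and t[3:].isdigit() and len(t) == 10):
                raise ValueError(f"{self.gene_id}: malformed GO id {t!r}")


@dataclass(frozen=True)
class NeighborLink:
    lncrna_id: str
    gene_id: str
    distance_bp: int
    relation: str  # upstream | downstream | overlapping

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValueError("distance must be non-negative")
        if self.relation not in {"upstream", "downstream", "overlapping"}:
            raise ValueError(f"invalid relation {self.relation!r}")


def place_transcripts(
    sequences: dict[str, str],
    genome: dict[str, str] | None = None,
    alignments: list[GenomePlacement] | None = None,
) -> tuple[list[GenomePlacement], set[str]]:
    """Assign at most one genomic locus per transcript.

    Exact-substring mode (``genome`` given) searches each chromosome in
    name order, forward strand first then reverse complement, and keeps
    the first match. Alignment mode (``alignments`` given) keeps the
    best placement per transcript by alignment length, ties broken by
    chromosome name then start. Returns placements plus unplaced ids.
    """
    if (genome is None) == (alignments is None):
        raise ValueError("provide exactly one of genome or alignments")

    placements: list[GenomePlacement] = []
    unplaced: set[str] = set()

    if genome is not None:
        chroms = sorted(genome)
        for tid in sequences:
            seq = sequences[tid].upper()
            hit = None
            for strand, probe in (("+", seq), ("-", reverse_complement(seq))):
                for chrom in chroms:
                    pos = genome[chrom].find(probe)
                    if pos != -1:
                        hit = GenomePlacement(tid, chrom, pos, pos + len(probe), strand)
                        break
                if hit:
                    break
            if hit:
                placements.append(hit)
            else:
                unplaced.add(tid)
    else:
        best: dict[str, GenomePlacement] = {}
        multi = 0
        for aln in alignments:
            if aln.transcript_id not in sequences:
                continue
            cur = best.get(aln.transcript_id)
            if cur is None:
                best[aln.transcript_id] = aln
            else:
                multi += 1
                key = (-(aln.end - aln.start), aln.chrom, aln.start)
                cur_key = (-(cur.end - cur.start), cur.chrom, cur.start)
                if key < cur_key:
                    best[aln.transcript_id] = aln
        if multi:
            logger.info("discarded %d secondary placements (one locus kept)", multi)
        placements = [best[t] for t in sequences if t in best]
        unplaced = {t for t in sequences if t not in best}

    frac = len(placements) / len(sequences) if sequences else 0.0
    logger.info("placed %d/%d transcripts (%.2f%%)", len(placements), len(sequences), 100 * frac)
    return placements, unplaced


def extract_neighbors(
    placements: list[GenomePlacement],
    genes: list[GeneAnnotation],
    window: int = 10_000,
) -> list[NeighborLink]:
    """Link each placed lncRNA to genes within ``window`` bp (inclusive).

    The gap between non-overlapping intervals is end-to-start distance;
    a gene whose gap is exactly ``window`` is linked. Overlapping
    intervals link at distance 0. Relations are reported relative to
    the lncRNA's strand ("+" assumed when unknown).
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    links: list[NeighborLink] = []
    for p in placements:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        # +1 on each side so boundary genes (gap == window) intersect the query
        for iv in sorted(tree.overlap(p.start - window - 1, p.end + window + 1)):
            g: GeneAnnotation = iv.data
            if g.start >= p.end:  # gene right of lncRNA
                gap = g.start - p.end
                genomic_side = "right"
            elif g.end <= p.start:  # gene left of lncRNA
                gap = p.start - g.end
                genomic_side = "left"
            else:
                gap = 0
                genomic_side = "overlap"
            if gap > window:
                continue
            if genomic_side == "overlap":
                relation = "overlapping"
            elif p.strand == "-":
                relation = "upstream" if genomic_side == "right" else "downstream"
            else:
                relation = "upstream" if genomic_side == "left" else "downstream"
            links.append(NeighborLink(p.transcript_id, g.gene_id, gap, relation))
    return links


@dataclass
class VennPartition:
    """Disjoint membership classes of up to three labeled sets."""

    labels: tuple[str, ...]
    partitions: dict[frozenset, set] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.partitions.values())

    def count(self, *labels: str) -> int:
        return len(self.partitions.get(frozenset(labels), set()))

    def percent(self, *labels: str) -> float:
        u = self.union_size
        return 100.0 * self.count(*labels) / u if u else 0.0

    def set_total(self, label: str) -> int:
        return sum(len(v) for k, v in self.partitions.items() if label in k)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "union": self.union_size,
            "partitions": {
                "&".join(sorted(k)): {
                    "count": len(v),
                    "percent_of_union": 100.0 * len(v) / self.union_size
                    if self.union_size
                    else 0.0,
                }
                for k, v in self.partitions.items()
            },
        }


def venn_partition(sets_by_label: dict[str, set]) -> VennPartition:
    """Partition 1-3 labeled sets into their 2^k - 1 disjoint classes."""
    labels = tuple(sets_by_label)
    if not 1 <= len(labels) <= 3:
        raise ValueError("venn_partition supports 1-3 sets")
    parts: dict[frozenset, set] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets_by_label[l] for l in combo))
            outside = set.union(
                set(), *(sets_by_label[l] for l in labels if l not in combo)
            )
            parts[frozenset(combo)] = inside - outside
    result = VennPartition(labels, parts)
    # internal consistency: disjoint and union-conserving
    all_members = [m for v in parts.values() for m in v]
    assert len(all_members) == len(set(all_members)), "partitions overlap"
    assert set(all_members) == set.union(*sets_by_label.values()), "union not conserved"
    return result
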