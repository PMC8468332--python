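"""Open-reading-frame scanning over unoriented transcript contigs.

An ORF is an ATG..stop stretch in a single frame with no internal stop;
the stop codon is included in the reported length. Because assembled
contigs carry no strand information, all six frames (three per strand)
are scanned and the single longest call is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfCall:
    """A single ORF call, with 0-based half-open offsets on the reported strand."""

    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int  # 0, 1 or 2
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp != self.end - self.start:
            raise ValueError("length_bp must equal end - start")
        if self.length_bp % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")


def _orfs_in_frame(seq: str, frame: int):
    """Yield (start, end) of complete ATG..stop ORFs in one frame.

    A codon containing N can be neither start nor stop and invalidates
    any ORF spanning it, so open starts are dropped when one is seen.
    """
    open_starts: list[int] = []
    n = len(seq)
    for pos in range(frame, n - 2, 3):
        codon = seq[pos : pos + 3]
        if "N" in codon:
            open_starts.clear()
            continue
        if codon in STOP_CODONS:
            # earliest open start gives the longest ORF ending here
            if open_starts:
                yield open_starts[0], pos + 3
            open_starts.clear()
        elif codon == START_CODON and not open_starts:
            # only the earliest start per stop matters for "longest"
            open_starts.append(pos)


def find_longest_orf(sequence: str) -> OrfCall | None:
    """Return the longest complete ORF over all six frames, or None.

    Ties are broken in favour of the forward strand, then the smallest
    start offset on the reported strand.
    """
    seq = sequence.upper()
    best: OrfCall | None = None
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            for start, end in _orfs_in_frame(s, frame):
                cand = OrfCall(start, end, strand, frame, end - start)
                if best is None or _better(cand, best):
                    best = cand
    return best


def _better(a: OrfCall, b: OrfCall) -> bool:
    ka = (a.length_bp, a.strand == "+", -a.start)
    kb = (b.length_bp, b.strand == "+", -b.start)
    return ka > kb
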