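"""The lncRNA mining cascade.

Assembled contigs are filtered in four ordered stages to yield putative
lncRNAs: (1) contigs with a protein/nucleotide homology hit are removed,
(2) contigs with mean read coverage below 50 are removed, (3) contigs
whose longest ORF exceeds 200 bp are removed, and (4) remaining contigs
classified as coding by the coding-potential model are removed. Each
stage is a pure predicate over a contig, so the cascade equals the
intersection of the per-stage keep-sets; the staged form is kept because
it yields the per-stage counts reported alongside the final set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coding_potential import (
    CodingPotentialClassifier,
    CodingPotentialFeatures,
    compute_features,
)

_VALID_BASES = frozenset("ACGTN")


@dataclass
class TranscriptRecord:
    """One assembled contig with its coverage and annotation status."""

    id: str
    sequence: str
    mean_coverage: float | None = None
    annotated: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 200:
            raise ValueError(
                f"contig {self.id}: length {len(self.sequence)} below the 200-nt "
                "assembly floor"
            )
        extra = set(self.sequence) - _VALID_BASES
        if extra:
            raise ValueError(f"contig {self.id}: invalid characters {sorted(extra)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CascadeReport:
    """Per-stage contig counts through the mining cascade."""

    total: int
    after_annotation: int
    after_coverage: int
    after_orf: int
    after_coding_potential: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.stage_counts()
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("stage counts must be non-increasing")

    def stage_counts(self) -> list[int]:
        return [
            self.total,
            self.after_annotation,
            self.after_coverage,
            self.after_orf,
            self.after_coding_potential,
        ]

    @property
    def putative_percent(self) -> float:
        return 100.0 * self.after_coding_potential / self.total if self.total else 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "after_annotation_filter": self.after_annotation,
            "after_coverage_filter": self.after_coverage,
            "after_orf_filter": self.after_orf,
            "putative_lncrnas": self.after_coding_potential,
            "putative_percent": self.putative_percent,
            "thresholds": self.thresholds,
        }


def filter_annotated(
    records: list[TranscriptRecord],
    hit_table: pd.DataFrame,
    evalue_threshold: float = 1e-3,
) -> list[TranscriptRecord]:
    """Drop contigs with a homology hit below the e-value threshold.

    ``hit_table`` is 12-column tabular homology output (query id in
    column 1, e-value in column 11). Order of survivors is preserved.
    """
    if len(hit_table) and hit_table.shape[1] != 12:
        raise ValueError(
            f"hit table must have 12 columns, found {hit_table.shape[1]}"
        )
    if len(hit_table):
        evalues = pd.to_numeric(hit_table.iloc[:, 10], errors="coerce")
        bad = np.flatnonzero(evalues.isna().to_numpy())
        if bad.size:
            raise ValueError(f"malformed e-value in hit table at line {bad[0] + 1}")
        annotated_ids = set(hit_table.iloc[:, 0][(evalues < evalue_threshold).to_numpy()])
    else:
        annotated_ids = set()
    return [r for r in records if r.id not in annotated_ids]


def filter_coverage(
    records: list[TranscriptRecord], min_cov: float = 50.0
) -> list[TranscriptRecord]:
    """Keep contigs with mean coverage >= min_cov (the boundary is kept)."""
    for r in records:
        if r.mean_coverage is None:
            raise ValueError(f"contig {r.id}: mean coverage missing")
    return [r for r in records if r.mean_coverage >= min_cov]


def filter_orf_length(
    records: list[TranscriptRecord],
    max_orf: int = 200,
    orf_lengths: dict[str, int] | None = None,
) -> list[TranscriptRecord]:
    """Keep contigs whose longest ORF is <= max_orf bp (none found: kept)."""
    from .orf import find_longest_orf

    kept = []
    for r in records:
        if orf_lengths is not None and r.id in orf_lengths:
            length = orf_lengths[r.id]
        else:
            orf = find_longest_orf(r.sequence)
            length = orf.length_bp if orf else 0
        if length <= max_orf:
            kept.append(r)
    return kept


def filter_coding_potential(
    records: list[TranscriptRecord],
    model: CodingPotentialClassifier,
    coding_freqs: dict[str, float],
    noncoding_freqs: dict[str, float],
) -> tuple[list[TranscriptRecord], dict[str, CodingPotentialFeatures]]:
    """Drop contigs the model scores at or above its cutoff."""
    if not records:
        return [], {}
    feats = {
        r.id: compute_features(r.sequence, coding_freqs, noncoding_freqs)
        for r in records
    }
    X = np.vstack([feats[r.id].as_array() for r in records])
    probs = model.predict_proba(X)[:, 1]
    scored = {
        r.id: CodingPotentialFeatures(
            feats[r.id].orf_length_bp,
            feats[r.id].orf_coverage,
            feats[r.id].fickett,
            feats[r.id].hexamer_bias,
            score=float(p),
        )
        for r, p in zip(records, probs)
    }
    kept = [r for r, p in zip(records, probs) if p < model.cutoff_]
    return kept, scored


def run_cascade(
    records: list[TranscriptRecord],
    hit_table: pd.DataFrame,
    model: CodingPotentialClassifier,
    coding_freqs: dict[str, float],
    noncoding_freqs: dict[str, float],
    evalue_threshold: float = 1e-3,
    min_cov: float = 50.0,
    max_orf: int = 200,
) -> tuple[list[TranscriptRecord], CascadeReport, dict[str, CodingPotentialFeatures]]:
    """Run the full four-stage mining cascade.

    Returns the putative lncRNA records, the per-stage count report and
    the coding-potential feature table of the contigs that reached the
    final stage.
    """
    s1 = filter_annotated(records, hit_table, evalue_threshold)
    s2 = filter_coverage(s1, min_cov)
    s3 = filter_orf_length(s2, max_orf)
    s4, scored = filter_coding_potential(s3, model, coding_freqs, noncoding_freqs)
    report = CascadeReport(
        total=len(records),
        after_annotation=len(s1),
        after_coverage=len(s2),
        after_orf=len(s3),
        after_coding_potential=len(s4),
        thresholds={
            "evalue": evalue_threshold,
            "min_cov": min_cov,
            "max_orf": max_orf,
            "cutoff": model.cutoff_,
        },
    )
    return s4, report, scored
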