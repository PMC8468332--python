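"""End-to-end orchestration of the lncRNA analysis on synthetic data.

``run_all`` generates every input with known ground truth, writes the
standard-format files, reads them back through the package's own
readers, and executes discovery -> genome placement -> neighbor
extraction -> differential expression -> GO enrichment -> correlation
-> qPCR validation, emitting per-stage artifacts and a run report whose
percentages are always recomputed from the underlying counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .coding_potential import compute_features, hexamer_frequencies, train_coding_model
from .correlation_linking import correlate_links
from .discovery import TranscriptRecord, run_cascade
from .enrichment import (
    GoDag,
    fisher_enrichment,
    propagate_annotations,
    reduce_most_specific,
)
from .expression_de import DEOptions, cluster_heatmap, compute_tpm, de_summary, run_de
from .genome_context import extract_neighbors, place_transcripts, venn_partition
from .orf import find_longest_orf, reverse_complement
from .qpcr import cross_platform_correlation, efficiency_from_dilution, relative_expression_table
from .synthetic_data import (
    REFERENCE_GENE,
    SyntheticConfig,
    generate_counts,
    generate_genome,
    generate_qpcr,
    generate_transcripts,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineThresholds:
    evalue: float = 1e-3
    min_cov: float = 50.0
    max_orf: int = 200
    cutoff: float = 0.5
    window: int = 10_000
    fc: float = 2.0
    fdr: float = 0.05
    alpha: float = 0.05

    def validate(self) -> None:
        for name in ("evalue", "min_cov", "max_orf", "window", "fc", "fdr", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class RunReport:
    """Per-stage counts of one pipeline run; percentages are derived,
    never stored."""

    seed: int
    total_contigs: int = 0
    putative_lncrnas: int = 0
    placed_lncrnas: int = 0
    de_counts: dict = field(default_factory=dict)  # stimulus -> {up, down}
    neighbor_genes: dict = field(default_factory=dict)  # stimulus -> count
    venn_de: dict = field(default_factory=dict)
    venn_neighbors: dict = field(default_factory=dict)
    enriched_terms: dict = field(default_factory=dict)
    correlated_pairs: int = 0
    significant_pairs: int = 0
    cross_platform_r: float | None = None
    timings: dict = field(default_factory=dict)

    @property
    def putative_percent(self) -> float:
        return 100.0 * self.putative_lncrnas / self.total_contigs if self.total_contigs else 0.0

    @property
    def placed_percent(self) -> float:
        return 100.0 * self.placed_lncrnas / self.putative_lncrnas if self.putative_lncrnas else 0.0

    def de_total(self, stimulus: str) -> int:
        d = self.de_counts.get(stimulus, {})
        return d.get("up", 0) + d.get("down", 0)

    def to_dict(self, include_timings: bool = False) -> dict:
        out = {
            "seed": self.seed,
            "total_contigs": self.total_contigs,
            "putative_lncrnas": self.putative_lncrnas,
            "putative_percent": self.putative_percent,
            "placed_lncrnas": self.placed_lncrnas,
            "placed_percent": self.placed_percent,
            "de_counts": {
                s: {**d, "total": self.de_total(s)} for s, d in self.de_counts.items()
            },
            "neighbor_genes": self.neighbor_genes,
            "venn_de": self.venn_de,
            "venn_neighbors": self.venn_neighbors,
            "enriched_terms": self.enriched_terms,
            "correlated_pairs": self.correlated_pairs,
            "significant_pairs": self.significant_pairs,
            "cross_platform_r": self.cross_platform_r,
        }
        if include_timings:
            out["timings"] = self.timings
        return out


def report_consistency_check(report: RunReport) -> list[tuple[str, bool]]:
    """Arithmetic identities every well-formed run report must satisfy."""
    checks: list[tuple[str, bool]] = []
    for stim, d in report.de_counts.items():
        checks.append(
            (f"de_up_plus_down_equals_total[{stim}]",
             d.get("up", 0) + d.get("down", 0) == report.de_total(stim))
        )
    for name, venn in (("venn_de", report.venn_de), ("venn_neighbors", report.venn_neighbors)):
        if venn:
            parts = venn.get("partitions", {})
            total = sum(p["count"] for p in parts.values())
            checks.append((f"{name}_partitions_sum_to_union", total == venn.get("union")))
    checks.append(
        ("placed_le_putative_le_total",
         report.placed_lncrnas <= report.putative_lncrnas <= report.total_contigs)
    )
    return checks


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Parenthesized tree text for a scipy-style linkage matrix."""
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    for step, (a, b, dist, _) in enumerate(linkage):
        nodes[n + step] = f"({nodes[int(a)]},{nodes[int(b)]}):{dist:.6g}"
    return nodes[n + len(linkage) - 1] + ";"


def _write_synthetic_inputs(cfg, outdir, genome, sequences, truth, hits, counts, lengths, dilution, ct):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_fasta(genome.chromosomes, outdir / "genome.fasta")
    hio.write_fasta(sequences, outdir / "contigs.fasta")
    pd.Series(truth.coverage, name="mean_coverage").rename_axis("contig_id").to_frame() \
        .to_csv(outdir / "coverage.tsv", sep="\t")
    hio.write_blast_tabular(hits, outdir / "hits.tsv")
    hio.write_gff3_genes(genome.genes, outdir / "genes.gff3")
    hio.write_gene2go_tsv(genome.gene2go, outdir / "gene2go.tsv")
    counts.rename_axis("feature_id").to_csv(outdir / "counts.tsv", sep="\t")
    lengths.rename("length").rename_axis("feature_id").to_frame() \
        .to_csv(outdir / "lengths.tsv", sep="\t")
    dilution.to_csv(outdir / "dilution_series.tsv", sep="\t", index=False)
    ct.to_csv(outdir / "ct_table.tsv", sep="\t", index=False)
    # truth tables for downstream inspection
    pd.DataFrame(
        {
            "contig_id": list(truth.contig_class),
            "class": list(truth.contig_class.values()),
            "annotated": [truth.annotated[c] for c in truth.contig_class],
        }
    ).to_csv(outdir / "truth_contigs.tsv", sep="\t", index=False)
    de_rows = [
        {"feature_id": f, "condition": c, "log2fc": v}
        for c, m in truth.lfc.items()
        for f, v in m.items()
    ]
    pd.DataFrame(de_rows, columns=["feature_id", "condition", "log2fc"]) \
        .to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    pd.DataFrame(truth.cis_pairs, columns=["lncrna_id", "gene_id", "sign"]) \
        .to_csv(outdir / "truth_cis_pairs.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
            fh, indent=2, sort_keys=True,
        )


def build_training_tables(sequences: dict[str, str], labels: dict[str, str]):
    """Hexamer frequency tables from labeled contigs: in-frame ORF
    hexamers for the coding class, all-frame hexamers for non-coding."""
    coding_orfs = []
    for cid, cls in labels.items():
        if cls != "coding":
            continue
        seq = sequences[cid]
        orf = find_longest_orf(seq)
        if orf is None:
            continue
        s = seq if orf.strand == "+" else reverse_complement(seq)
        coding_orfs.append(s[orf.start : orf.end])
    noncoding = [sequences[c] for c, cls in labels.items() if cls == "noncoding"]
    return (
        hexamer_frequencies(coding_orfs, step=3),
        hexamer_frequencies(noncoding, step=1),
    )


def run_all(
    cfg: SyntheticConfig,
    outdir,
    thresholds: PipelineThresholds | None = None,
    run_qpcr: bool = True,
) -> RunReport:
    """Execute the full synthetic-mode pipeline; see module docstring."""
    th = thresholds or PipelineThresholds()
    th.validate()
    cfg.validate()
    outdir = Path(outdir)
    report = RunReport(seed=cfg.seed)
    clock: dict[str, float] = {}

    def tick(stage):
        clock[stage] = time.perf_counter()

    def tock(stage):
        report.timings[stage] = round(time.perf_counter() - clock[stage], 3)

    # ---- synthesis ----------------------------------------------------
    tick("synthesis")
    genome = generate_genome(cfg)
    sequences, truth, hits = generate_transcripts(cfg, genome)
    counts, lengths = generate_counts(cfg, truth, sequences, genome.genes)
    dilution, ct = generate_qpcr(cfg, truth)
    _write_synthetic_inputs(cfg, outdir, genome, sequences, truth, hits, counts, lengths, dilution, ct)
    tock("synthesis")

    # ---- read back through the standard-format readers ----------------
    genome_seqs = hio.read_fasta(outdir / "genome.fasta")
    contig_seqs = hio.read_fasta(outdir / "contigs.fasta")
    coverage = hio.read_coverage_tsv(outdir / "coverage.tsv")
    hit_table = hio.read_blast_tabular(outdir / "hits.tsv")
    genes = hio.read_gff3_genes(outdir / "genes.gff3")
    gene2go = hio.read_gene2go_tsv(outdir / "gene2go.tsv")
    counts = hio.read_counts_tsv(outdir / "counts.tsv")
    lengths = hio.read_coverage_tsv(outdir / "lengths.tsv")
    dilution = pd.read_csv(outdir / "dilution_series.tsv", sep="\t")
    ct = pd.read_csv(outdir / "ct_table.tsv", sep="\t")

    # ---- discovery ----------------------------------------------------
    tick("discovery")
    records = [
        TranscriptRecord(cid, seq, mean_coverage=float(coverage[cid]))
        for cid, seq in contig_seqs.items()
    ]
    coding_freqs, noncoding_freqs = build_training_tables(contig_seqs, truth.contig_class)
    feats, labels = [], []
    for cid in contig_seqs:
        feats.append(compute_features(contig_seqs[cid], coding_freqs, noncoding_freqs).as_array())
        labels.append(1 if truth.contig_class[cid] == "coding" else 0)
    model = train_coding_model(np.array(feats), np.array(labels), cutoff=th.cutoff)
    putative, cascade_report, scored = run_cascade(
        records, hit_table, model, coding_freqs, noncoding_freqs,
        evalue_threshold=th.evalue, min_cov=th.min_cov, max_orf=th.max_orf,
    )
    putative_ids = [r.id for r in putative]
    report.total_contigs = cascade_report.total
    report.putative_lncrnas = cascade_report.after_coding_potential
    hio.write_fasta({r.id: r.sequence for r in putative}, outdir / "putative_lncrnas.fasta")
    pd.DataFrame(
        [
            {
                "contig_id": cid,
                "orf_length_bp": f.orf_length_bp,
                "orf_coverage": f.orf_coverage,
                "fickett": f.fickett,
                "hexamer_bias": f.hexamer_bias,
                "coding_score": f.score,
            }
            for cid, f in scored.items()
        ]
    ).to_csv(outdir / "coding_potential_features.tsv", sep="\t", index=False)
    with open(outdir / "cascade_report.json", "w") as fh:
        json.dump(cascade_report.to_dict(), fh, indent=2, sort_keys=True)
    tock("discovery")

    # ---- placement and neighbors --------------------------------------
    tick("genome_context")
    placements, unplaced = place_transcripts(
        {i: contig_seqs[i] for i in putative_ids}, genome=genome_seqs
    )
    report.placed_lncrnas = len(placements)
    hio.write_bed_placements(placements, outdir / "placements.bed")
    links = extract_neighbors(placements, genes, window=th.window)
    pd.DataFrame(
        [
            {"lncrna_id": l.lncrna_id, "gene_id": l.gene_id,
             "distance_bp": l.distance_bp, "relation": l.relation}
            for l in links
        ],
        columns=["lncrna_id", "gene_id", "distance_bp", "relation"],
    ).to_csv(outdir / "neighbors.tsv", sep="\t", index=False)
    tock("genome_context")

    # ---- differential expression --------------------------------------
    tick("expression_de")
    conditions = cfg.sample_conditions()
    de = run_de(
        counts, lengths, conditions, control=cfg.control,
        options=DEOptions(fc_threshold=th.fc, fdr_threshold=th.fdr),
    )
    tpm = compute_tpm(counts, lengths)
    putative_set = set(putative_ids)
    de_lnc: dict[str, set[str]] = {}
    de_gene: dict[str, set[str]] = {}
    for stim, df in de.items():
        df.rename_axis("feature_id").to_csv(outdir / f"de_{stim}.tsv", sep="\t")
        flagged = set(df.index[df["de_flag"]])
        de_lnc[stim] = flagged & putative_set
        de_gene[stim] = flagged & set(truth.gene_ids)
        sub = df.loc[sorted(de_lnc[stim])]
        report.de_counts[stim] = {
            "up": int((sub["direction"] == "up").sum()),
            "down": int((sub["direction"] == "down").sum()),
        }
    venn_de = venn_partition(de_lnc)
    report.venn_de = venn_de.to_dict()

    all_de_lnc = sorted(set.union(*de_lnc.values())) if de_lnc else []
    if len(all_de_lnc) >= 2:
        cond_means = pd.DataFrame(
            {c: tpm.loc[all_de_lnc, conditions.index[conditions == c]].mean(axis=1)
             for c in cfg.conditions}
        )
        link_mat, order, norm = cluster_heatmap(cond_means)
        pd.Series(order, name="feature_id").to_csv(outdir / "heatmap_order.tsv", sep="\t", index=False)
        (outdir / "heatmap_linkage.txt").write_text(linkage_to_newick(link_mat, all_de_lnc) + "\n")
        norm.rename_axis("feature_id").to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    tock("expression_de")

    # ---- neighbor genes of DE lncRNAs, Venn and GO enrichment ----------
    tick("enrichment")
    neighbor_genes = {
        stim: {l.gene_id for l in links if l.lncrna_id in de_lnc[stim]}
        for stim in de_lnc
    }
    report.neighbor_genes = {s: len(g) for s, g in neighbor_genes.items()}
    venn_ng = venn_partition(neighbor_genes)
    report.venn_neighbors = venn_ng.to_dict()
    with open(outdir / "venn_de.json", "w") as fh:
        json.dump(venn_de.to_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "venn_neighbors.json", "w") as fh:
        json.dump(venn_ng.to_dict(), fh, indent=2, sort_keys=True)

    with resources.as_file(
        resources.files("hemolnc.data").joinpath("go_mini_synthetic.obo")
    ) as obo_path:
        dag = GoDag.from_obo(str(obo_path))
    full_map = propagate_annotations(gene2go, dag)
    background = set(truth.gene_ids)
    for stim, study in neighbor_genes.items():
        if not study:
            report.enriched_terms[stim] = 0
            continue
        results = fisher_enrichment(study, background, full_map, dag)
        top_bp = reduce_most_specific(results, dag, alpha=th.alpha)
        report.enriched_terms[stim] = sum(r.p < th.alpha for r in results)
        pd.DataFrame(
            [
                {"term": r.term, "namespace": r.namespace, "k": r.k, "n": r.n,
                 "K": r.K, "N": r.N, "p": r.p, "most_specific": r.most_specific}
                for r in results
            ]
        ).to_csv(outdir / f"enrichment_{stim}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"term": r.term, "p": r.p} for r in top_bp]
        ).to_csv(outdir / f"enrichment_top_bp_{stim}.tsv", sep="\t", index=False)
    tock("enrichment")

    # ---- lncRNA / neighbor-gene correlation (LPS arm) -------------------
    tick("correlation")
    lps_lnc = de_lnc.get("LPS", set())
    lps_gene = de_gene.get("LPS", set())
    corr_results, corr_matrix = ([], pd.DataFrame())
    if lps_lnc and lps_gene:
        corr_results, corr_matrix = correlate_links(tpm, links, lps_lnc, lps_gene)
    report.correlated_pairs = len(corr_results)
    report.significant_pairs = sum(
        1 for r in corr_results if r.defined and r.pearson_p < 0.05
    )
    pd.DataFrame(
        [
            {"lncrna_id": r.lncrna_id, "gene_id": r.gene_id,
             "pearson_r": r.pearson_r, "pearson_p": r.pearson_p,
             "spearman_rho": r.spearman_rho, "spearman_p": r.spearman_p,
             "n_samples": r.n_samples}
            for r in corr_results
        ],
        columns=["lncrna_id", "gene_id", "pearson_r", "pearson_p",
                 "spearman_rho", "spearman_p", "n_samples"],
    ).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    if len(corr_matrix):
        corr_matrix.rename_axis("feature_id").to_csv(outdir / "correlation_matrix.tsv", sep="\t")
    tock("correlation")

    # ---- qPCR validation ------------------------------------------------
    if run_qpcr:
        tick("qpcr")
        effs = {}
        for primer, grp in dilution.groupby("primer"):
            effs[primer] = efficiency_from_dilution(grp, primer_id=primer).efficiency
        rel = relative_expression_table(ct, effs, ref_gene=REFERENCE_GENE, control=cfg.control)
        # per (target, stimulus) qPCR FC: geometric mean ratio across individuals
        qpcr_fc = (
            rel.groupby(["target", "stimulus"])["ratio"]
            .apply(lambda r: float(np.exp(np.log(r).mean())))
        )
        pairs = [
            (t, s) for s, targets in truth.validation_targets.items() for t in targets
        ]
        idx = pd.MultiIndex.from_tuples(pairs)
        rnaseq_fc = pd.Series(
            [de[s].loc[t, "fc"] for t, s in pairs], index=idx, dtype=float
        )
        qpcr_matched = pd.Series(
            [qpcr_fc.loc[(t, s)] for t, s in pairs], index=idx, dtype=float
        )
        # qPCR ratios are on the ratio scale; convert to the signed scale
        qpcr_signed = qpcr_matched.map(lambda x: x if x >= 1 else -1.0 / x)
        r, p = cross_platform_correlation(rnaseq_fc, qpcr_signed)
        report.cross_platform_r = r
        out = pd.DataFrame(
            {
                "lncrna_id": [t for t, _ in pairs],
                "stimulus": [s for _, s in pairs],
                "rnaseq_fc": rnaseq_fc.to_numpy(),
                "qpcr_fc": qpcr_signed.to_numpy(),
            }
        )
        out.to_csv(outdir / "qpcr_validation.tsv", sep="\t", index=False)
        tock("qpcr")

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    for name, ok in report_consistency_check(report):
        if not ok:
            logger.warning("consistency check failed: %s", name)
    return report
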