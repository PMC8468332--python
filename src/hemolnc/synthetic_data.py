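"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:
a random genome with non-overlapping annotated genes, coding contigs
with long ORFs and codon-biased (hence hexamer-biased) composition,
non-coding contigs with short ORFs and uniform composition (a third of
them genome-placeable), negative-binomial counts over 3 replicates x 4
conditions with planted condition-specific fold changes (LPS carrying
the largest DE fraction), cis lncRNA-gene pairs within 10 kb with
coupled expression, and Ct tables consistent with the planted
expression under a known amplification efficiency.

Every generator stage is a pure function of (config, master seed);
per-stage child seeds are derived by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .genome_context import GeneAnnotation, GenomePlacement
from .orf import find_longest_orf

_SEED_GENOME = 1
_SEED_TRANSCRIPTS = 2
_SEED_COUNTS = 3
_SEED_QPCR = 4

REFERENCE_GENE = "18S"
REFERENCE_GENE_LENGTH = 1800
REFERENCE_GENE_MEAN = 5000.0
NEIGHBOR_WINDOW = 10_000


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the modeled study: 3 biological replicates per
    condition (12 samples), an LPS-dominant transcriptional response,
    about a third of lncRNAs placeable on the genome, and NB counts
    with biological-scale overdispersion.
    """

    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 150
    n_coding_contigs: int = 300
    n_noncoding_contigs: int = 300
    placeable_fraction: float = 0.33
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("control", "LPS", "polyIC", "betaglucan")
    control: str = "control"
    de_fraction_per_condition: dict = field(
        default_factory=lambda: {"LPS": 0.25, "polyIC": 0.08, "betaglucan": 0.10}
    )
    planted_log2fc_range: tuple[float, float] = (1.5, 4.0)
    dispersion: float = 0.2
    mean_expression_range: tuple[float, float] = (20.0, 1000.0)
    cis_pair_fraction: float = 0.25
    cis_coupling: float = 1.0  # exponent tying cis-gene means to lncRNA counts
    # residual dispersion of a cis gene given its lncRNA, as a fraction of
    # the common dispersion: the shared biological variability is carried
    # by the lncRNA counts, so only technical-scale noise remains
    cis_residual_dispersion: float = 0.25
    efficiency_true: float = 1.95
    # free-choice knobs (see methods note)
    low_coverage_fraction: float = 0.05
    noncoding_length_range: tuple[int, int] = (300, 1000)
    coding_orf_codons: tuple[int, int] = (80, 300)
    utr_length_range: tuple[int, int] = (50, 150)
    gene_length_range: tuple[int, int] = (500, 3000)
    max_rejection_tries: int = 200
    ct_noise_sd: float = 0.25
    efficiency_jitter: tuple[float, float] = (-0.03, 0.02)
    individual_lognoise_sd: float = 0.15
    n_individuals: int = 3
    n_validation_per_stimulus: int = 4
    dilution_points: int = 5
    dilution_step: float = 5.0

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_replicates": self.n_replicates,
            "n_individuals": self.n_individuals,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0 or self.n_coding_contigs < 0 or self.n_noncoding_contigs < 0:
            raise ValueError("entity counts must be non-negative")
        for name, p in [
            ("placeable_fraction", self.placeable_fraction),
            ("cis_pair_fraction", self.cis_pair_fraction),
            ("low_coverage_fraction", self.low_coverage_fraction),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.conditions.count(self.control) != 1 or self.control not in self.conditions:
            raise ValueError("conditions must contain exactly one control label")
        if self.control in self.de_fraction_per_condition:
            raise ValueError("the control condition cannot have a DE fraction")
        for c, f in self.de_fraction_per_condition.items():
            if c not in self.conditions or not 0 <= f <= 1:
                raise ValueError(f"bad DE fraction for condition {c!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 1 < self.efficiency_true <= 2:
            raise ValueError("efficiency_true must lie in (1, 2]")
        lo, hi = self.planted_log2fc_range
        if not 0 < lo <= hi:
            raise ValueError("planted_log2fc_range must be positive and ordered")

    @property
    def stimuli(self) -> list[str]:
        return [c for c in self.conditions if c != self.control]

    @property
    def sample_names(self) -> list[str]:
        return [f"{c}_{r}" for c in self.conditions for r in range(1, self.n_replicates + 1)]

    def sample_conditions(self) -> pd.Series:
        return pd.Series(
            {f"{c}_{r}": c for c in self.conditions for r in range(1, self.n_replicates + 1)}
        )


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    genes: list[GeneAnnotation]
    gene2go: dict[str, set[str]]


@dataclass
class SyntheticTruth:
    """Planted ground truth, the oracle for every downstream test."""

    contig_class: dict[str, str]  # coding | noncoding
    annotated: dict[str, bool]
    coverage: dict[str, float]
    placement: dict[str, GenomePlacement | None]
    lfc: dict[str, dict[str, float]]  # condition -> feature -> planted log2 FC
    cis_pairs: list[tuple[str, str, int]]  # (lncRNA, gene, correlation sign)
    gene_ids: list[str] = field(default_factory=list)
    base_means: dict[str, float] = field(default_factory=dict)
    validation_targets: dict[str, list[str]] = field(default_factory=dict)
    qpcr_efficiencies: dict[str, float] = field(default_factory=dict)

    def is_de(self, feature: str, condition: str) -> bool:
        return feature in self.lfc.get(condition, {})

    def de_features(self, condition: str) -> set[str]:
        return set(self.lfc.get(condition, {}))

    def planted_lfc(self, feature: str, condition: str) -> float:
        return self.lfc.get(condition, {}).get(feature, 0.0)

    def contigs_of_class(self, cls: str) -> list[str]:
        return [c for c, k in self.contig_class.items() if k == cls]

    def check_invariants(self) -> None:
        if self.lfc.get("control"):
            raise AssertionError("DE flags planted for the control condition")
        for lnc, gene, sign in self.cis_pairs:
            if self.contig_class.get(lnc) != "noncoding":
                raise AssertionError(f"cis pair {lnc} is not a noncoding contig")
            if self.placement.get(lnc) is None:
                raise AssertionError(f"cis pair {lnc} is not placeable")
            if sign not in (-1, 1):
                raise AssertionError("cis pair sign must be +-1")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _load_codon_table() -> tuple[list[str], np.ndarray]:
    text = (
        resources.files("hemolnc.data")
        .joinpath("codon_usage_synthetic.tsv")
        .read_text()
    )
    codons, freqs = [], []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        codon, freq = line.split("\t")
        if float(freq) > 0:
            codons.append(codon)
            freqs.append(float(freq))
    w = np.array(freqs)
    return codons, w / w.sum()


def _go_term_pool() -> list[str]:
    from .enrichment import GoDag

    with resources.as_file(
        resources.files("hemolnc.data").joinpath("go_mini_synthetic.obo")
    ) as p:
        dag = GoDag.from_obo(str(p))
    roots = {"GO:0008150", "GO:0003674", "GO:0005575"}
    return sorted(t for t in dag.graph.nodes if t not in roots)


def generate_genome(cfg: SyntheticConfig) -> SyntheticGenome:
    """Random chromosomes with non-overlapping annotated genes.

    Genes are distributed round-robin over chromosomes and packed with
    Dirichlet-distributed gaps; each gene receives 1-3 GO terms from
    the bundled miniature DAG. Raises when the requested genes cannot
    fit on the chromosomes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _SEED_GENOME)
    chroms = {
        f"chr{i + 1}": _random_dna(rng, cfg.chrom_length)
        for i in range(cfg.n_chromosomes)
    }
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(cfg.n_genes):
        per_chrom[f"chr{(i % cfg.n_chromosomes) + 1}"] += 1

    genes: list[GeneAnnotation] = []
    term_pool = _go_term_pool()
    idx = 0
    for chrom, n in per_chrom.items():
        if n == 0:
            continue
        lengths = rng.integers(*cfg.gene_length_range, size=n, endpoint=True)
        free = cfg.chrom_length - int(lengths.sum())
        if free < n + 1:  # need at least 1 bp between/around genes
            raise ValueError(
                f"infeasible packing: {n} genes of total length {int(lengths.sum())} "
                f"do not fit on a {cfg.chrom_length}-bp chromosome"
            )
        gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * free).astype(int)
        pos = 0
        for j in range(n):
            pos += int(gaps[j])
            start, end = pos, pos + int(lengths[j])
            idx += 1
            genes.append(
                GeneAnnotation(
                    gene_id=f"gene_{idx:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            pos = end
    gene2go = {
        g.gene_id: set(
            rng.choice(term_pool, size=rng.integers(1, 4), replace=False).tolist()
        )
        for g in genes
    }
    for g in genes:
        g.go_terms = tuple(sorted(gene2go[g.gene_id]))
    return SyntheticGenome(chroms, genes, gene2go)


def _sample_coding_sequence(rng, cfg, codons, codon_p) -> str:
    n_codons = int(rng.integers(*cfg.coding_orf_codons, endpoint=True))
    orf = "ATG" + "".join(rng.choice(codons, size=n_codons, p=codon_p))
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    utr5 = _random_dna(rng, int(rng.integers(*cfg.utr_length_range, endpoint=True)))
    utr3 = _random_dna(rng, int(rng.integers(*cfg.utr_length_range, endpoint=True)))
    return utr5 + orf + stop + utr3


def _sample_short_orf_sequence(rng, cfg, length: int, source=None) -> tuple[str, int]:
    """Rejection-sample a sequence whose longest ORF is <= 200 bp.

    ``source`` draws a candidate (used to pull genome substrings);
    default is uniform random DNA. Returns (sequence, start) where
    start is meaningful only for genome substrings.
    """
    for _ in range(cfg.max_rejection_tries):
        if source is None:
            seq, start = _random_dna(rng, length), -1
        else:
            seq, start = source()
        orf = find_longest_orf(seq)
        if orf is None or orf.length_bp <= 200:
            return seq, start
    raise RuntimeError(
        "rejection sampling exhausted: could not draw a sequence with "
        f"longest ORF <= 200 bp in {cfg.max_rejection_tries} tries"
    )


def generate_transcripts(
    cfg: SyntheticConfig, genome: SyntheticGenome
) -> tuple[dict[str, str], SyntheticTruth, pd.DataFrame]:
    """Contig sequences, ground truth and the homology hit table.

    Coding contigs carry a codon-biased ORF longer than 200 bp and are
    all annotated (one hit each, e-value far below 1e-3); non-coding
    contigs are rejection-sampled to a longest ORF of at most 200 bp
    and round(placeable_fraction x n) of them are exact genome
    substrings. DE status and cis pairs are planted here so that
    cis-paired lncRNAs land within 10 kb of their partner gene.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _SEED_TRANSCRIPTS)
    codons, codon_p = _load_codon_table()

    coding_ids = [f"coding_{i + 1:04d}" for i in range(cfg.n_coding_contigs)]
    noncoding_ids = [f"lnc_{i + 1:04d}" for i in range(cfg.n_noncoding_contigs)]
    gene_ids = [g.gene_id for g in genome.genes]

    n_placeable = int(round(cfg.placeable_fraction * cfg.n_noncoding_contigs))
    placeable = list(rng.choice(noncoding_ids, size=n_placeable, replace=False)) if n_placeable else []

    # --- planted DE ---------------------------------------------------
    lfc: dict[str, dict[str, float]] = {c: {} for c in cfg.stimuli}
    all_contigs = coding_ids + noncoding_ids

    def draw_lfc() -> float:
        lo, hi = cfg.planted_log2fc_range
        return float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)

    # cis pairs: placeable noncoding contigs forced DE under LPS with a
    # positive-coupled partner gene sharing the same planted fold change
    n_cis = min(int(round(cfg.cis_pair_fraction * len(placeable))), len(gene_ids))
    cis_lncs = list(placeable[:n_cis])
    cis_genes = list(rng.choice(gene_ids, size=n_cis, replace=False)) if n_cis else []
    cis_pairs: list[tuple[str, str, int]] = []
    for lnc, gene in zip(cis_lncs, cis_genes):
        v = draw_lfc()
        lfc["LPS"][lnc] = v
        lfc["LPS"][gene] = v  # positive coupling
        cis_pairs.append((lnc, gene, 1))

    for cond, frac in cfg.de_fraction_per_condition.items():
        n_de = int(round(frac * len(all_contigs)))
        pool = [f for f in all_contigs if f not in lfc[cond]]
        n_extra = max(n_de - len(lfc[cond]), 0)
        for f in rng.choice(pool, size=min(n_extra, len(pool)), replace=False):
            lfc[cond][f] = draw_lfc()
        # background DE genes beyond the cis-coupled ones
        gene_pool = [g for g in gene_ids if g not in lfc[cond]]
        n_gene_de = int(round(frac * len(gene_ids)))
        n_gene_extra = max(n_gene_de - sum(g in lfc[cond] for g in gene_ids), 0)
        for g in rng.choice(gene_pool, size=min(n_gene_extra, len(gene_pool)), replace=False):
            lfc[cond][g] = draw_lfc()

    # --- sequences and placements -------------------------------------
    gene_by_id = {g.gene_id: g for g in genome.genes}
    chrom_names = sorted(genome.chromosomes)
    sequences: dict[str, str] = {}
    placement: dict[str, GenomePlacement | None] = {}

    for cid in coding_ids:
        sequences[cid] = _sample_coding_sequence(rng, cfg, codons, codon_p)
        placement[cid] = None

    cis_gene_of = dict(zip(cis_lncs, cis_genes))
    for nid in noncoding_ids:
        length = int(rng.integers(*cfg.noncoding_length_range, endpoint=True))
        if nid in cis_gene_of:
            g = gene_by_id[cis_gene_of[nid]]
            chrom_seq = genome.chromosomes[g.chrom]
            lo = max(g.start - NEIGHBOR_WINDOW - length, 0)
            hi = max(min(g.end + NEIGHBOR_WINDOW, len(chrom_seq) - length), lo)

            def source(lo=lo, hi=hi, chrom_seq=chrom_seq):
                s = int(rng.integers(lo, hi + 1))
                return chrom_seq[s : s + length], s

            seq, start = _sample_short_orf_sequence(rng, cfg, length, source)
            placement[nid] = GenomePlacement(nid, g.chrom, start, start + length, "+")
        elif nid in placeable:
            def source(chrom_seq=None, length=length):
                chrom = chrom_names[rng.integers(0, len(chrom_names))]
                cs = genome.chromosomes[chrom]
                s = int(rng.integers(0, len(cs) - length + 1))
                return cs[s : s + length], (chrom, s)

            seq, where = _sample_short_orf_sequence(rng, cfg, length, source)
            chrom, start = where
            placement[nid] = GenomePlacement(nid, chrom, start, start + length, "+")
        else:
            seq, _ = _sample_short_orf_sequence(rng, cfg, length)
            placement[nid] = None
        sequences[nid] = seq

    # --- coverage ------------------------------------------------------
    coverage = {}
    for cid in all_contigs:
        if rng.random() < cfg.low_coverage_fraction:
            coverage[cid] = float(rng.uniform(5.0, 49.5))
        else:
            coverage[cid] = 50.0 + float(rng.lognormal(3.5, 1.0))

    # --- homology hits for the coding (annotated) contigs ---------------
    hit_rows = []
    for i, cid in enumerate(coding_ids):
        L = len(sequences[cid])
        hit_rows.append(
            [
                cid,
                f"sp|SYNP{i + 1:05d}|SYNTHETIC",
                round(float(rng.uniform(40, 95)), 1),
                L // 3,
                int(rng.integers(0, 20)),
                0,
                1,
                L,
                1,
                L // 3,
                float(10.0 ** -rng.uniform(5, 30)),
                round(float(rng.uniform(50, 300)), 1),
            ]
        )
    from .io import BLAST_COLUMNS

    hits = pd.DataFrame(hit_rows, columns=BLAST_COLUMNS)

    truth = SyntheticTruth(
        contig_class={**{c: "coding" for c in coding_ids}, **{n: "noncoding" for n in noncoding_ids}},
        annotated={**{c: True for c in coding_ids}, **{n: False for n in noncoding_ids}},
        coverage=coverage,
        placement=placement,
        lfc=lfc,
        cis_pairs=cis_pairs,
        gene_ids=gene_ids,
    )
    truth.check_invariants()
    return sequences, truth, hits


def generate_counts(
    cfg: SyntheticConfig,
    truth: SyntheticTruth,
    sequences: dict[str, str],
    genes: list[GeneAnnotation],
) -> tuple[pd.DataFrame, pd.Series]:
    """NB count matrix (contigs + genes + reference gene) x 12 samples.

    count(feature i, sample s) ~ NB(mean mu_i * 2^lfc(i, cond(s)),
    dispersion phi); base means are log-uniform over the configured
    range and recorded in ``truth.base_means``. A cis-paired gene's
    per-sample mean is additionally multiplied by (realized lncRNA
    count / expected lncRNA mean)^cis_coupling, so the pair co-varies
    within conditions as well as across them. Returns (counts, feature
    lengths).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _SEED_COUNTS)
    features = list(truth.contig_class) + truth.gene_ids + [REFERENCE_GENE]
    lo, hi = cfg.mean_expression_range
    mus = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(features)))
    truth.base_means = dict(zip(features, mus.astype(float)))
    truth.base_means[REFERENCE_GENE] = REFERENCE_GENE_MEAN

    samples = cfg.sample_names
    cond_of = cfg.sample_conditions()
    cis_partner = {gene: lnc for lnc, gene, _ in truth.cis_pairs}

    def draw(mu: float, phi: float) -> int:
        if phi < 1e-8:
            return int(rng.poisson(mu))
        r = 1.0 / phi
        return int(rng.negative_binomial(r, r / (r + mu)))

    mat = np.zeros((len(features), len(samples)), dtype=np.int64)
    row_of = {f: i for i, f in enumerate(features)}
    for i, f in enumerate(features):
        mu0 = truth.base_means[f]
        for j, s in enumerate(samples):
            cond = cond_of[s]
            mu = mu0 * 2.0 ** truth.planted_lfc(f, cond)
            phi = cfg.dispersion
            if f in cis_partner:
                lnc = cis_partner[f]
                expected = truth.base_means[lnc] * 2.0 ** truth.planted_lfc(lnc, cond)
                realized = max(mat[row_of[lnc], j], 1)
                mu *= (realized / expected) ** cfg.cis_coupling
                phi *= cfg.cis_residual_dispersion
            mat[i, j] = draw(mu, phi)
    counts = pd.DataFrame(mat, index=features, columns=samples)

    gene_len = {g.gene_id: g.end - g.start for g in genes}
    lengths = pd.Series(
        {
            f: len(sequences[f]) if f in sequences
            else gene_len.get(f, REFERENCE_GENE_LENGTH)
            for f in features
        },
        dtype=float,
    )
    return counts, lengths


def generate_qpcr(
    cfg: SyntheticConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dilution series and Ct tables for the 12-lncRNA validation arm.

    Per stimulus, ``n_validation_per_stimulus`` planted-DE non-coding
    contigs are selected. Ct = intercept - log_E(expression) + noise,
    with per-individual lognormal expression variability and technical
    triplicates; the reference gene is non-DE by construction. Returns
    (dilution series table, Ct table); the chosen targets and true
    per-primer efficiencies are recorded on ``truth``.
    """
    cfg.validate()
    if not truth.base_means:
        raise ValueError("generate_counts must run before generate_qpcr")
    rng = np.random.default_rng(cfg.seed + _SEED_QPCR)

    noncoding = set(truth.contigs_of_class("noncoding"))
    targets: dict[str, list[str]] = {}
    for stim in cfg.stimuli:
        pool = sorted(truth.de_features(stim) & noncoding)
        if len(pool) < cfg.n_validation_per_stimulus:
            raise ValueError(
                f"fewer than {cfg.n_validation_per_stimulus} planted DE lncRNAs "
                f"for stimulus {stim!r}"
            )
        targets[stim] = list(
            rng.choice(pool, size=cfg.n_validation_per_stimulus, replace=False)
        )
    truth.validation_targets = targets

    primers = sorted({t for ts in targets.values() for t in ts}) + [REFERENCE_GENE]
    jlo, jhi = cfg.efficiency_jitter
    eff = {
        p: float(np.clip(cfg.efficiency_true + rng.uniform(jlo, jhi), 1.05, 2.0))
        for p in primers
    }
    truth.qpcr_efficiencies = eff
    intercepts = {p: float(rng.uniform(18, 24)) for p in primers}

    dil_rows = []
    dilutions = [cfg.dilution_step**-k for k in range(cfg.dilution_points)]
    for p in primers:
        for d in dilutions:
            base = intercepts[p] - np.log(d) / np.log(eff[p])
            for rep in (1, 2, 3):
                dil_rows.append(
                    {
                        "primer": p,
                        "dilution": d,
                        "replicate": rep,
                        "ct": base + rng.normal(0, cfg.ct_noise_sd),
                    }
                )
    dilution_df = pd.DataFrame(dil_rows)

    ct_rows = []
    for ind in range(1, cfg.n_individuals + 1):
        for cond in cfg.conditions:
            for p in primers:
                if p == REFERENCE_GENE:
                    x = REFERENCE_GENE_MEAN
                else:
                    x = truth.base_means[p] * 2.0 ** truth.planted_lfc(p, cond)
                x *= np.exp(rng.normal(0, cfg.individual_lognoise_sd))
                base = intercepts[p] - np.log(x) / np.log(eff[p])
                for rep in (1, 2, 3):
                    ct_rows.append(
                        {
                            "individual": f"mussel_{ind}",
                            "condition": cond,
                            "target": p,
                            "replicate": rep,
                            "ct": base + rng.normal(0, cfg.ct_noise_sd),
                        }
                    )
    ct_df = pd.DataFrame(ct_rows)
    return dilution_df, ct_df
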