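"""The synthetic-data generator: determinism, planted structure and
distributional behaviour."""

import numpy as np
import pandas as pd
import pytest

from hemolnc.orf import find_longest_orf
from hemolnc.synthetic_data import (
    NEIGHBOR_WINDOW,
    REFERENCE_GENE,
    SyntheticConfig,
    generate_counts,
    generate_genome,
    generate_qpcr,
    generate_transcripts,
)


def small_cfg(**kw):
    defaults = dict(
        seed=7, n_chromosomes=2, chrom_length=120_000, n_genes=30,
        n_coding_contigs=40, n_noncoding_contigs=40,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SyntheticConfig().validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"placeable_fraction": 1.5},
            {"dispersion": 0.0},
            {"efficiency_true": 2.5},
            {"conditions": ("LPS", "polyIC")},
            {"planted_log2fc_range": (0.0, 2.0)},
            {"n_replicates": 0},
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticConfig(**kw).validate()


class TestGenome:
    def test_zero_genes_gives_empty_annotation(self):
        g = generate_genome(small_cfg(n_genes=0))
        assert g.genes == [] and g.gene2go == {}

    def test_deterministic_given_seed(self):
        a = generate_genome(small_cfg())
        b = generate_genome(small_cfg())
        assert a.chromosomes == b.chromosomes
        assert [(g.gene_id, g.start, g.end, g.strand) for g in a.genes] == [
            (g.gene_id, g.start, g.end, g.strand) for g in b.genes
        ]
        assert a.gene2go == b.gene2go

    def test_gene_intervals_within_bounds_and_disjoint(self):
        cfg = small_cfg(n_genes=50)
        g = generate_genome(cfg)
        by_chrom = {}
        for gene in g.genes:
            assert 0 <= gene.start < gene.end <= cfg.chrom_length
            by_chrom.setdefault(gene.chrom, []).append((gene.start, gene.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2  # exhaustive non-overlap scan

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            generate_genome(small_cfg(chrom_length=5000, n_genes=30))

    def test_every_gene_has_go_terms(self):
        g = generate_genome(small_cfg())
        assert all(g.gene2go[gene.gene_id] for gene in g.genes)


class TestTranscripts:
    @pytest.fixture(scope="class")
    def bundle(self):
        cfg = small_cfg()
        genome = generate_genome(cfg)
        return cfg, genome, *generate_transcripts(cfg, genome)

    def test_placeable_count_forced_by_rounding(self):
        cfg = small_cfg(n_noncoding_contigs=100, n_genes=40, chrom_length=250_000)
        genome = generate_genome(cfg)
        cfg.placeable_fraction = 0.33
        _, truth, _ = generate_transcripts(cfg, genome)
        placed = [c for c, p in truth.placement.items() if p is not None]
        assert len(placed) == 33

    def test_noncoding_orfs_at_most_200(self, bundle):
        _, _, sequences, truth, _ = bundle
        for cid in truth.contigs_of_class("noncoding"):
            orf = find_longest_orf(sequences[cid])
            assert orf is None or orf.length_bp <= 200

    def test_coding_orfs_exceed_200(self, bundle):
        _, _, sequences, truth, _ = bundle
        for cid in truth.contigs_of_class("coding"):
            assert find_longest_orf(sequences[cid]).length_bp > 200

    def test_zero_coding_contigs(self):
        cfg = small_cfg(n_coding_contigs=0)
        genome = generate_genome(cfg)
        _, truth, hits = generate_transcripts(cfg, genome)
        assert truth.contigs_of_class("coding") == []
        assert hits.empty

    def test_annotation_flags_follow_class(self, bundle):
        _, _, _, truth, hits = bundle
        for cid, cls in truth.contig_class.items():
            assert truth.annotated[cid] == (cls == "coding")
        assert set(hits["qseqid"]) == set(truth.contigs_of_class("coding"))
        assert (hits["evalue"] < 1e-3).all()

    def test_placements_are_exact_substrings(self, bundle):
        _, genome, sequences, truth, _ = bundle
        for cid, p in truth.placement.items():
            if p is None:
                continue
            assert genome.chromosomes[p.chrom][p.start : p.end] == sequences[cid]

    def test_cis_pairs_within_window_by_brute_force(self, bundle):
        _, genome, _, truth, _ = bundle
        gene_by_id = {g.gene_id: g for g in genome.genes}
        assert truth.cis_pairs
        for lnc, gene, _ in truth.cis_pairs:
            p = truth.placement[lnc]
            g = gene_by_id[gene]
            assert p.chrom == g.chrom
            gap = max(g.start - p.end, p.start - g.end, 0)
            assert gap <= NEIGHBOR_WINDOW

    def test_deterministic_given_seed(self):
        cfg = small_cfg()
        genome = generate_genome(cfg)
        s1, t1, h1 = generate_transcripts(cfg, genome)
        s2, t2, h2 = generate_transcripts(cfg, genome)
        assert s1 == s2
        assert t1.lfc == t2.lfc and t1.cis_pairs == t2.cis_pairs
        assert h1.equals(h2)

    def test_hexamer_class_separability_sign(self, synth):
        from hemolnc.coding_potential import hexamer_bias
        from hemolnc.pipeline import build_training_tables

        cf, nf = build_training_tables(synth.sequences, synth.truth.contig_class)
        coding = [
            hexamer_bias(synth.sequences[c], cf, nf)
            for c in synth.truth.contigs_of_class("coding")[:50]
        ]
        noncoding = [
            hexamer_bias(synth.sequences[c], cf, nf)
            for c in synth.truth.contigs_of_class("noncoding")[:50]
        ]
        assert np.mean(coding) - np.mean(noncoding) > 0


class TestCounts:
    def test_poisson_limit_variance_mean_ratio(self):
        cfg = small_cfg(dispersion=1e-9, n_coding_contigs=150, n_noncoding_contigs=150)
        genome = generate_genome(cfg)
        sequences, truth, _ = generate_transcripts(cfg, genome)
        counts, _ = generate_counts(cfg, truth, sequences, genome.genes)
        ctrl = counts[[c for c in counts.columns if c.startswith("control")]]
        # pool the variance/mean ratio across non-DE features
        ratios = []
        for f in counts.index:
            row = ctrl.loc[f]
            if row.mean() > 0:
                ratios.append(row.var(ddof=1) / row.mean())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_no_planted_de_means_within_three_se(self):
        cfg = small_cfg(de_fraction_per_condition={"LPS": 0.0, "polyIC": 0.0, "betaglucan": 0.0},
                        cis_pair_fraction=0.0)
        genome = generate_genome(cfg)
        sequences, truth, _ = generate_transcripts(cfg, genome)
        counts, _ = generate_counts(cfg, truth, sequences, genome.genes)
        phi = cfg.dispersion
        n = counts.shape[1]
        outside = 0
        for f in counts.index:
            mu = truth.base_means[f]
            se = np.sqrt((mu + phi * mu**2) / n)
            if abs(counts.loc[f].mean() - mu) > 3 * se:
                outside += 1
        # 3-SE exceedances should be rare (<~1% for Gaussian; allow slack)
        assert outside / len(counts.index) < 0.03

    def test_non_de_feature_identical_law_across_conditions(self):
        # regenerating with the same seed reproduces identical columns,
        # and a non-DE feature's generating mean is condition-independent
        cfg = small_cfg()
        genome = generate_genome(cfg)
        sequences, truth, _ = generate_transcripts(cfg, genome)
        c1, _ = generate_counts(cfg, truth, sequences, genome.genes)
        c2, _ = generate_counts(cfg, truth, sequences, genome.genes)
        assert c1.equals(c2)
        non_de = next(
            f for f in truth.contig_class
            if all(not truth.is_de(f, c) for c in cfg.stimuli)
        )
        assert all(truth.planted_lfc(non_de, c) == 0.0 for c in cfg.conditions)

    def test_reference_gene_present_and_non_de(self, synth):
        assert REFERENCE_GENE in synth.counts.index
        assert all(
            not synth.truth.is_de(REFERENCE_GENE, c) for c in synth.cfg.conditions
        )


class TestQpcr:
    def test_dilution_slope_recovers_perfect_doubling(self):
        cfg = small_cfg(
            efficiency_true=2.0, ct_noise_sd=0.0, efficiency_jitter=(0.0, 0.0),
            de_fraction_per_condition={"LPS": 0.3, "polyIC": 0.3, "betaglucan": 0.3},
        )
        genome = generate_genome(cfg)
        sequences, truth, _ = generate_transcripts(cfg, genome)
        generate_counts(cfg, truth, sequences, genome.genes)
        dilution, _ = generate_qpcr(cfg, truth)
        from scipy.stats import linregress

        for primer, grp in dilution.groupby("primer"):
            mean_ct = grp.groupby("dilution")["ct"].mean()
            slope = linregress(np.log10(mean_ct.index.to_numpy()), mean_ct.to_numpy()).slope
            assert slope == pytest.approx(-1 / np.log10(2), abs=1e-6)

    def test_insufficient_de_lncrnas_error(self):
        cfg = small_cfg(
            de_fraction_per_condition={"LPS": 0.25, "polyIC": 0.0, "betaglucan": 0.1},
            cis_pair_fraction=0.0,
        )
        genome = generate_genome(cfg)
        sequences, truth, _ = generate_transcripts(cfg, genome)
        generate_counts(cfg, truth, sequences, genome.genes)
        with pytest.raises(ValueError, match="fewer than"):
            generate_qpcr(cfg, truth)

    def test_validation_targets_are_planted_de_noncoding(self, synth):
        for stim, targets in synth.truth.validation_targets.items():
            assert len(targets) == synth.cfg.n_validation_per_stimulus
            for t in targets:
                assert synth.truth.contig_class[t] == "noncoding"
                assert synth.truth.is_de(t, stim)
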