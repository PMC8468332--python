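# Methods

This note records the statistical models, the defaults and the design
choices behind `hemolnc`, and what the synthetic benchmark does and
does not demonstrate.

## The mining cascade

A putative lncRNA is an assembled contig (≥ 200 nt, the assembly floor;
the canonical lncRNA length threshold is therefore enforced as a
validation invariant rather than a filter stage) that survives four
ordered filters:

1. **Annotation.** Contigs with any homology hit at e-value < 10⁻³ in a
   12-column tabular hit file are removed. The package consumes the hit
   file rather than running a search: database versions and search
   engines are outside its scope.
2. **Coverage.** Contigs with mean read coverage < 50 are removed; the
   boundary value 50.0 is kept (the rule deletes strictly below 50).
3. **ORF length.** Contigs whose longest ORF exceeds 200 bp are
   removed; a contig with no complete ORF is kept, and a 200-bp ORF is
   kept. An ORF requires both an ATG and a stop codon in the same
   frame with no internal stop, and the stop is included in the length
   — the common convention in coding-potential tools, chosen because it
   gives an unambiguous boundary. All six frames are scanned because
   assembled contigs are unoriented; ties prefer the forward strand,
   then the smallest start. Codons containing N can be neither start
   nor stop and sever any ORF spanning them.
4. **Coding potential.** A logistic regression on four features — ORF
   length (bp), ORF coverage (ORF length / contig length), the Fickett
   TESTCODE statistic, and the hexamer usage bias — is trained on
   labeled contigs and applied at a probability cutoff of 0.5
   (configurable; no published cutoff exists for this system, and an
   optional Youden-J tuning on a held-out split is provided). The
   classifier always trains on user-provided labeled data rather than
   shipping a fixed foreign model, because coding statistics are
   clade-specific.

Each stage is a pure predicate, so the cascade equals the intersection
of per-stage keep-sets; the staged order is kept for its per-stage
counts. The Fickett tables ship as a JSON data file and are interpreted
at run time: position parameters are max/(min+1) over the three codon
positions per base, content parameters are base fractions, both mapped
through descending threshold bins and combined with the published
weights. Hexamer bias is the mean over in-frame (step-3) hexamers of
log(F_c/F_nc), computed inside the longest ORF, or over the whole
sequence in frame 0 when there is no ORF; hexamers containing N are
skipped. The logistic fit is Newton/IRLS on internally standardized
features (tolerance 1e-8, ≤ 100 iterations) with an L2 ridge fallback
(λ = 1e-3) under quasi-perfect separation — separation is the expected
regime when classes are cleanly separable, as in the synthetic data.

## Genome context

Internally every interval is 0-based half-open; GFF3 (1-based closed),
BED and SAM conversions happen only at file boundaries. Placement
assigns at most one locus per transcript: exact-substring search
(forward strand then reverse complement, chromosomes in name order) in
synthetic mode, or best-by-alignment-length selection over provided
BED/SAM alignments, discarding secondary placements with a logged
count. Neighbor extraction links a placed lncRNA to every gene whose
interval lies within 10,000 bp ("up to 10 kb" read as ≤, boundary
inclusive), strand-agnostically, using an interval tree; distance is
the end-to-start gap (0 for overlaps) and the upstream/downstream
relation is reported relative to the lncRNA's strand ("+" assumed when
unknown). Venn partitioning of 1–3 labeled sets asserts disjointness
and union conservation on every call.

## Differential expression

Counts are assumed NB distributed: Var = μ + φμ². For each stimulus
vs. control contrast (3 + 3 replicates):

- **Library equalization.** The exact test conditions on equal library
  sizes; columns are scaled to the geometric-mean library size with
  half-to-even rounding. This deterministic surrogate replaces the
  original quantile adjustment and is exact in expectation for the
  group totals.
- **Common dispersion (qCML).** The likelihood of each feature's
  within-group counts conditional on their group total does not depend
  on the feature mean; summing these conditional log-likelihoods over
  features and groups and maximizing over φ by golden-section search on
  [1e-6, 10] (tolerance 1e-6) gives the common-dispersion estimate.
  Only the common estimate is used — no tagwise shrinkage, since the
  modeled analysis names only the exact test.
- **Exact test.** With equalized libraries, group sums are
  A ~ NB(n_A μ, φ/n_A), B ~ NB(n_B μ, φ/n_B); conditional on
  t = a + b the p-value is the sum of the probabilities of all splits
  whose conditional probability is ≤ that of the observed split
  (two-sided by probability mass; masses within 1e-12 relative count as
  ties), with μ̂ = t/(n_A+n_B). Below φ = 1e-8 the Poisson limit is
  used, where the conditional law is Binomial(t, n_A/(n_A+n_B)).
  t = 0 returns p = 1.
- **Gating.** Fold change is computed on per-group mean TPM with an
  additive pseudo-TPM of 1.0 (zero handling is unstated in the modeled
  analysis; this is the package's choice), reported signed (−k means
  k-fold down). The DE gate is |FC| > 2 ∧ BH-FDR < 0.05, adjusted
  within each contrast separately (mirroring three independent runs).
  BH is the FDR procedure because the analysis names only "FDR".
- **Clustering.** DE lncRNAs are clustered on per-condition mean TPM
  with the Lance–Williams centroid update applied to squared Pearson
  distances (d = 1 − r), smallest-creation-index tie-breaks,
  zero-variance rows pinned at the maximum distance 2 with a warning.
  The implementation is in-package because library centroid linkage
  presumes Euclidean observations, whereas the prescribed distance is
  correlation-based.

## Enrichment, correlation, qPCR

GO annotations are propagated to all is_a ancestors (true-path rule);
each term present in the study set is tested with the one-sided Fisher
exact test (over-representation; "enriched" is one-sided), with the
background defaulting to all annotated genes; no multiple-testing
correction is applied to enrichment p-values by default (a p < 0.05
cutoff is the stated practice; BH is available). Significant terms with
no significant descendant are flagged most specific; the top-20
biological-process selection is sorted by p. Pathway-style flat
categories reuse the same counting without a DAG.

Correlation uses scipy's Pearson and Spearman (midranks; t-based
p-values); "significant correlation" means two-sided p < 0.05,
uncorrected, over all 12 samples. An exact-permutation Spearman p is
available behind a flag for n ≤ 8 (full enumeration; beyond that the
factorial cost is prohibitive and the t approximation is used).

qPCR efficiency is the CT-slope method (OLS of mean Ct on log₁₀
dilution, technical replicates averaged first; E = 10^(−1/slope),
accepted range (1, 2.2]). Relative expression is the Pfaffl ratio with
ΔCt = Ct(control) − Ct(treated), the control being the same
individual's unstimulated well; per-target fold changes aggregate
individuals by the geometric mean of ratios (ratios are
multiplicative). For cross-platform correlation, signed fold changes
−k are mapped to 1/k before taking log₁₀.

## The synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
at desk scale (defaults): 2 chromosomes × 300 kb with 150
non-overlapping genes; 300 coding + 300 non-coding contigs; 3
replicates × 4 conditions; NB dispersion φ = 0.2 (biological-scale
overdispersion); base means log-uniform on [20, 1000]; planted |log₂FC|
uniform on [1.5, 4] with random sign; DE fractions LPS 0.25, β-glucans
0.10, poly I:C 0.08 (LPS-dominant, as observed in hemocytes); 33% of
non-coding contigs placeable (exact genome substrings); 25% of
placeable lncRNAs cis-paired with a gene within 10 kb; 5% of contigs
below the coverage-50 floor; qPCR efficiency 1.95 with ±0.02–0.03
per-primer jitter, Ct noise SD 0.25, 3 individuals with lognormal
(σ = 0.15) individual variability. Coding contigs are ATG + codons
drawn from a bundled synthetic codon-usage table + stop, flanked by
random UTRs; non-coding contigs are rejection-sampled (budget 200) to a
longest ORF ≤ 200 bp. The coverage law (lognormal above the floor) is a
free choice — the real coverage distribution is not published.

Cis pairs are planted as LPS-DE lncRNAs whose partner gene shares the
planted fold change; the gene's per-sample mean is additionally scaled
by (realized lncRNA count / expected mean)^κ with κ = 1 and a reduced
residual dispersion (0.25 φ), reflecting that the shared biological
variability of a genuine cis pair is carried by the pair, leaving
smaller independent noise. Ct values are intercept − log_E(expression)
+ noise, so the qPCR arm is consistent with the planted expression by
construction.

What passing tests show: the machinery recovers planted structure under
the assumed model (NB counts, exact placements, clean class
separation). What they do not show: robustness to assembly artifacts,
multi-mapping, spliced placements, annotation errors, batch effects, or
coding/non-coding boundaries blurrier than the planted ones — real
contigs are noisier on every axis.

## Problem sizes and numerical notes

Simulation-based checks use 2000 features (dispersion recovery, null
type-I control, KS uniformity), 600 contigs (discovery recovery),
500 × 500 random intervals (neighbor oracle), 200 random contingency
tuples (Fisher oracle), and all group totals t ≤ 30 × φ ∈ {0, 0.1, 1}
(exact-test oracle) — sizes chosen so the whole suite runs in well
under a minute per check on one core. Conditional log-likelihoods are
computed via log-Γ; exact-test pmfs in log space with log-sum-exp
normalization. Degenerate inputs are handled explicitly: all-zero
count columns (zero TPM + warning), zero totals (p = 1), zero-variance
expression rows (flagged, not NaN-propagated), genes that cannot pack
onto a chromosome (explicit error), rejection-sampling exhaustion
(explicit error naming the constraint).

## Known limitations

- Only a common NB dispersion is estimated; strong per-feature
  dispersion heterogeneity will miscalibrate the exact test.
- Exact-substring placement is intentionally noise-free; real
  placement requires an aligner upstream and the BED/SAM reading path.
- The enrichment reducer implements the descendant-significance rule;
  other "most specific" semantics exist in commercial tools.
- The coding-potential classifier is only as good as its labeled
  training set; with none available, the cascade degrades to the first
  three filters.
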