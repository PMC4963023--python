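# Methods

`xenorna` re-implements, as a tested pipeline over synthetic data, the
analysis chain used for dual-species xenograft RNA-seq experiments — a
human tumor grown in a mouse host, profiled in a single sequencing run —
together with the companion statistics for cytokine panels, phagocytosis
assays and tumor growth. This note records the models, the defaults and
why, the numerical choices, and what the synthetic data does and does
not show.

## Two-species read disambiguation

**Model.** A xenograft lysate yields reads from two transcriptomes that
share regions of high conservation. After competitive alignment of the
same reads against both references, each read *pair* is assigned one of
four fates: unique to the human reference, unique to the mouse
reference, ambiguous (any hit in both species, discarded), or unmapped.
The discard rule is strict and unconditional — no score-based rescue,
no probabilistic reassignment — because a read compatible with both
species carries no usable species information and keeping it would bias
whichever compartment it were given to.

**Design choices.**

* The unit is the read pair, and cross-species evidence from either
  mate (including mate 1 hitting human while mate 2 hits mouse)
  discards the pair. The library is paired-end; splitting mates would
  double-count fragments. A per-read variant of the statistics is
  available through `classify_set` by feeding single-mate streams, but
  the pair-level numbers are the ones reported.
* `min_mapq` defaults to 0: any reported hit counts as evidence.
  Secondary alignments count like any other hit.
* SAM files omit unaligned reads, so the denominator for "fraction
  mapped" cannot come from the SAM streams alone; `classify_sam` takes
  a FASTQ manifest (or an explicit total) to count fully unmapped pairs.
* Records whose FLAG carries inconsistent mate bits are demoted to
  AMBIGUOUS with a warning — the safe direction for a discard rule.

## Synthetic reads: what the generator emulates

The generator stands in for the study conditions: 50-nt paired-end
fragments over a two-species reference, with a mixture profile of 70%
of pairs mapping to at least one reference, 7% mapping to both species,
and 80% of the species-assignable pairs human (`study_profile`). Those
three fractions are the planted truth the classifier is scored against.

The surrogate references are transcript pairs derived from a common
ancestor. A designated segment (default 20% of a 1-kb transcript) is
kept verbatim identical; the remainder is mutated per-position at 35%
divergence and then *screened*: any read-length window touching
non-shared sequence that still occurs verbatim in the other species is
re-mutated until none remains. The screen makes "maps to both
references" exactly equivalent to "drawn from a shared segment", so
truth labels are clean: classification can be compared to truth
label-for-label, and the tests require exact agreement.

Alignments are emitted directly from the known placement of each
fragment rather than by running an aligner. This keeps the pipeline
hermetic and the truth exact; `classify_sam` can equally ingest SAM
produced by a real aligner. Consequences to keep in mind:

* "Unmappable" pairs are random sequence with no alignment record —
  they reproduce the ~30% non-mapping mass without modelling base
  quality, adapter content or error profiles.
* Reads are placed uniformly within the legal positions of a uniformly
  chosen transcript; there is no expression structure, fragment-length
  distribution, or splice-aware placement in the read simulator.
* Species-unique pairs are placed so that *neither* mate lies wholly
  inside a shared segment; without that constraint a mate falling
  entirely in conserved sequence would legitimately hit both species
  and the pair's truth label would be wrong, not the classifier.

Passing the mapping-statistics checks therefore shows that the
classifier implements the discard rule correctly and that the mixture
arithmetic is right — not that any particular aligner would achieve the
same fractions on real tissue.

## Composite gene length and RPKM

A gene's composite length is the summed length of the non-overlapping
exon groups obtained as the interval union of all exons of all of its
transcripts. The merge treats touching intervals as one group and is
idempotent; it is verified against a per-base boolean-array union on
1,000 random gene models. GTF input (1-based inclusive) is converted to
0-based half-open coordinates internally; BED output keeps the 0-based
convention. Strand is ignored (unstranded library chemistry).

RPKM is `1e9 * C / (N_s * L)` with `L` the composite length and `N_s`
the per-sample total of pairs uniquely assigned to *that species*. The
denominator choice matters in a xenograft: normalizing the mouse
compartment by the total mapped reads would deflate host expression by
the (much larger) human read mass, so each compartment is quantified
against its own assigned total. Counting is fragment-level: a pair
counts once, to a gene, if its alignments hit transcripts of exactly
one gene; pairs spanning two genes are tallied gene-ambiguous and
dropped from counts (conservation `counted + gene-ambiguous +
intergenic = assigned` is asserted by construction).

## Differential expression

The test is the classic conditional NB exact test for two-group count
comparisons, assembled from:

* **Size factors** — median of ratios to the per-gene geometric mean,
  over genes with nonzero counts in every sample. A `pseudo_reference`
  fallback (geometric mean over nonzero entries only) covers sparse
  matrices; it is opt-in so silent behavior changes cannot occur.
* **Dispersions** — method-of-moments per gene on normalized counts,
  `alpha = max(0, (v - m*xi)/m^2)` with `v` the replicate variance
  pooled across replicated groups, `m` the normalized mean and `xi` the
  mean reciprocal size factor; a quadratic log-log trend is fit through
  the positive estimates; the working dispersion is
  `max(gene-wise, trend)`. The max-sharing rule is deliberately
  conservative: with 5 replicates per group the gene-wise estimates are
  noisy, and taking the upper envelope trades a little power for
  control of false positives. The quadratic trend replaces local
  regression; over the two decades of means the generator produces, the
  difference is negligible and the fit has no tuning parameters.
* **Exact test** — condition on the total `K = k_A + k_B` of the two
  group sums; under the null both sums are NB with means proportional
  to the summed size factors and variances
  `mu + alpha * q0^2 * sum(s_j^2)`. The p-value sums the joint
  probabilities of all splits no more probable than the observed one,
  normalized by the total over all `K + 1` splits. Enumeration is
  exact (verified against an independent brute-force oracle to 1e-12
  for all totals up to 50) and vectorized in log space, with the
  Poisson limit taken when the variance does not exceed the mean.
* **Multiple testing** — Benjamini–Hochberg; the default significance
  cutoff is `padj < 0.1`, exposed as a parameter. Genes with all-zero
  counts are excluded before testing and returned flagged, untested.

Calibration is checked by simulation: on null NB data (1,000 genes,
5 per group, dispersion 0.1) the raw p-values pass a KS uniformity test
and the type-I rate at 0.05 sits within 3 binomial SE; with 4-fold
changes planted in 10% of genes, sensitivity is ≥ 0.8 and the empirical
FDR stays within 1.5× the nominal 0.1.

The count generator plants the study's qualitative time-course: 10% of
human genes DE at 4 h and 8 h under the effector-competent antibody,
nothing at 168 h, nothing under the effector-silent IgG4 variant, and
twice the DE fraction in the mouse compartment (the host inflammatory
response is broader than the tumor's). Baseline means are log-normal
(median 50, log-sd 1) — a stand-in, since per-gene depth distributions
are not derivable from a per-sample read total; planted fold changes
are N(2, 0.5) in log2 with random sign; library sizes vary log-normally
(sd 0.15) unless multipliers are given explicitly.

## Downstream-effects scoring

Two generic machineries over a directional gene-set knowledge base
(process → member genes, each with the regulation direction expected
when the process is active):

* one-sided hypergeometric (Fisher) over-representation of the DE list
  in the process membership;
* the activation z-score
  `z = (N_consistent - N_inconsistent) / sqrt(N)` over the `N` member
  genes present in the DE results, where a gene is consistent when the
  sign of its fold change matches the expected direction. `|z| >= 2`
  calls Increased/Decreased; processes with no scoreable member are
  reported unscored rather than given z = 0.

This is the *unweighted* form of the published downstream-effects
statistic: per-edge weights come from curated commercial content and
are not reproducible, so all edges count equally. Results sort by
descending z with ties broken by process id, so output is stable.
Commercial knowledge-base content, and therefore any published table of
process z-scores, is out of scope by construction.

## Cytokine panel statistics

The simulated panel mirrors the dual-kit layout: 29 human and 27 mouse
analytes with 22 shared under a common name, measured on every lysate of
a compound × time × replicate design. Planted responders are elevated at
8 h and back at baseline by 168 h.

* **Clustering** — Ward linkage on Euclidean distances between samples,
  computed on the 22 shared analytes only (the two species must be
  described by the same features), after `log10(x + 1)` transformation
  and per-analyte z-scoring. The log transform is required because
  bead-panel concentrations span orders of magnitude; standardization
  keeps abundant analytes from dominating the distance. Censored
  (below-detection) values are imputed at LOD/2 and flagged.
* **Factorial model** — per analyte, ordinary least squares of
  log-concentration on species, compound, time and the three pairwise
  interactions, with type-II F tests (the reproducible choice for
  possibly unbalanced fixed-effect designs; on balanced designs type-II
  equals type-I, which a test asserts). Analytes covered by one panel
  only are fit without the species terms and flagged. Saturated designs
  raise rather than silently dropping terms.

## Phagocytosis and tumor growth

* `PI = (engulfed / M) * (M_double_positive / M) * 100`, with
  `engulfed = initial - final` tumor counts and `M` the macrophages
  counted. The record carries both tumor counts; which image defines
  "initial" is the caller's decision. The simulator engulfs each tumor
  cell independently and assigns engulfed cells to uniformly chosen
  macrophages (default 1:2 tumor:macrophage plating).
* Assay group comparisons use two-way ANOVA with interaction and
  Bonferroni-adjusted pairwise post-tests on the pooled residual mean
  square (comparisons between levels of the first factor within each
  level of the second, the usual layout for grouped assay data).
* `TV = length * width^2 / 2` (mm³, long and short diameters). TGI is
  the baseline-corrected form
  `100 * (1 - (T(d) - T(0)) / (C(d) - C(0)))`; it is undefined (raises)
  when the control arm did not grow. Published in-vivo percentages
  depend on animal data and are context here, not targets.

## Problem sizes and determinism

Every generator is a pure function of (config, seed); all randomness
flows through one `numpy` Generator per call. The test suite and the
acceptance script use fixed seeds and desk-scale sizes chosen for
statistical adequacy: 200,000 read pairs for the mapping fractions
(3-binomial-SE bands of ±0.3 percentage points), 1,000–2,000 genes for
DE calibration and size-factor recovery, 100 seeded replicates for the
clustering and ranking checks, 400 replicate fits for factorial
calibration. Larger runs change nothing but the width of the sampling
bands.

## Known limitations

* The read simulator has no error model, no quality-driven mapping loss
  and no splice structure; mapping fractions are planted, not emergent
  from sequence evolution.
* The DE module covers two-group exact-test contrasts only — no GLMs,
  covariates, or shrinkage-era estimators, matching the method it
  re-implements.
* The activation score is unweighted and the knowledge base synthetic;
  agreement with any curated-content scores is not claimed.
* Factorial models are fixed-effects OLS; repeated-measures or
  mixed-effects structure is out of scope.
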