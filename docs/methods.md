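# Methods

## Scope and model

`quantbench` evaluates how well RNA-seq quantification measures preserve
replicate agreement.  The unit of analysis is a *model*: a set of replicate
samples (the same tumor implanted into different mice, the same library
re-sequenced, etc.).  Six measure scenarios are compared on identical input:
TPM, FPKM, median-of-ratios-normalized counts, TMM-normalized counts,
per-gene Z-scores of log2(TPM+1), and TMM applied directly to TPM columns.

The quantification formulas (TPM, FPKM, their interconversion, the Z-score)
operate on RSEM's expected counts and effective lengths.  Effective length is
used as the length term throughout because that is the length on which
RSEM's own TPM/FPKM columns are defined; an internal consistency check in
the test suite recomputes both columns from (expected_count,
effective_length) and requires agreement within 0.5% for expressed genes.
Genes with effective length 0 must have zero counts; they receive TPM = FPKM
= 0 and are excluded from denominators.

## Normalization

**Median-of-ratios.**  The reference is the per-gene geometric mean of
counts over all samples; a gene with a zero in any sample drops out of the
reference.  The factor is the median of count/reference ratios, taken on the
ratio scale (with an even number of reference genes this interpolates
arithmetically between the two central ratios; interpolating in log space
would differ in the 5th decimal).  Expected counts are rounded to the
nearest integer first, mirroring import paths that feed fractional RSEM
counts into integer-count frameworks; the effect is negligible and covered
by a test.

**TMM.**  For sample *s* against reference *r* with library sizes *N*, using
genes positive in both: M = log2((q_s/N_s)/(q_r/N_r)), A = ½·log2 of the
product.  Trimming is rank-based with average ranks and inclusive bounds
(lower bound ⌊n·trim⌋+1, upper bound n+1−⌊n·trim⌋, ties kept), defaults 30%
on M and 5% on A.  Weights are the inverse delta-method variance
(N−q)/(N·q) summed over the two samples.  The automatic reference is the
sample whose 75th-percentile count fraction is closest to the mean of those
fractions.  Factors are rescaled to geometric mean 1 so they are comparable
across reference choices.  Normalized counts are q/(N·factor) rescaled by
the mean library size; TMM-on-TPM simply divides each TPM column by its
factor (library sizes are the fixed 10^6 column sums).  A brute-force,
independently coded TMM (explicit loops, pairwise-counting ranks) lives in
the test suite and pins the implementation at rel. 1e-10 under default
trims.

## Clustering concordance

Dissimilarities are 1−Pearson (over all genes; range [0,2]) or Euclidean.
Linkage follows the Ward.D2 convention: the Lance–Williams recurrence runs
on squared dissimilarities and heights are reported unsquared, so 1−Pearson
heights may exceed 2.  Ties in the merge criterion break on the smallest
(cluster_a, cluster_b) id pair, making dendrograms fully deterministic —
necessary because synthetic data can produce exact ties.  Complete linkage
is available as a sensitivity option.  Clustering input is log2(x+1) for
linear measures and raw values for Z-scores; a `--cluster-scale linear` flag
exists for sensitivity analyses.  Correctness is pinned against an
independent hierarchical-clustering implementation on random matrices.

A model is *concordant* when some internal dendrogram node's leaf set equals
exactly the model's replicate set (an exclusive clade).  This formalizes
"replicates cluster together" in a rotation-invariant, testable way.  The
two dendrogram summaries are the discordant-model count and the maximum
merge height.

## CV and ICC

CV is computed on the *linear* scale (SD with n−1 over mean), per gene
within one model's replicates, restricted to genes with positive mean there;
CV of log-scale values would be near-degenerate since log means can approach
0.  Quartiles use linear interpolation.

ICC uses the one-way random-effects estimator ICC(1):
(MS_b − MS_e)/(MS_b + (k−1)MS_e), where MS_b is the between-unit and MS_e
the within-unit residual mean square.  Inputs are log2(x+1) values — the
pseudocount-1, base-2 convention used consistently across the package.
Negative estimates (expected when the true ICC is near 0 and k is small) are
clamped to 0; the raw value is kept for audit.  ICC_g uses all replicates of
a model (k = 3 or 4).  ICC_m requires a balanced layout, so every model is
truncated to the minimum replicate count, keeping each model's *first* r
samples in sample-sheet order; genes whose truncated matrix is all-identical
are recorded as undefined and excluded from the median.  The estimator is
pinned to a brute-force ANOVA oracle at 1e-10 on random matrices.

Top-k abundance ranks genes per model by summed TPM over that model's
replicates (ties broken lexicographically by gene id) and reports each
replicate's fraction of the 10^6 TPM total carried by the top k (default 5).

## Synthetic data generator

The generator emulates a PDX-repository-like replicate design and is the
package's test bed; its defaults are the benchmark conditions.

* Sizes: 20 models, 3 replicates each with one 4-replicate model (61
  samples), 2000 genes, 5 dominant genes, 4 contaminated models.
* Gene propensities: θ_mg = exp(base_g + u_mg), base_g ~
  N(4.0, 2.0²) shared by all models (natural-log scale), u_mg ~ N(0, 0.21²)
  per model.  The shared baseline keeps between-model distances commensurate
  with replicate noise, as in real transcriptomes where all samples share
  most of their expression program; the marginal per-model distribution stays
  log-normal with sd ≈ 2.  The model-effect scale 0.21 was set so that the
  generator exhibits its defining qualitative behavior (below) on a 10-seed
  panel.
* Lengths: dominant genes uniform on 120–1500 bases (short, rRNA/mito-like);
  other genes log-normal (median 2 kb, log-sd 0.5) clamped to [200, 100000];
  effective length = length − 200, floored at 1.
* Contamination: per replicate, the dominant genes take a molar fraction f
  of the pool, split evenly; f ~ U(0.05, 0.5) in contaminated models and
  U(0.08, 0.12) in clean ones.  The remaining 1−f is allocated
  proportionally to θ.  Because TPM is compositional, every non-dominant
  gene's TPM scales by (1−f), so replicate-to-replicate variation in f
  shifts whole profiles — the mechanism that degrades TPM.  Dominant genes
  are short, so their *read* share (∝ molar fraction × effective length) is
  much smaller than their molar share; FPKM is therefore hit less than TPM,
  and count-based normalizations, driven by the unchanged majority of genes,
  absorb the shift entirely.
* Counts: reads are allocated ∝ molar fraction × effective length; library
  size is log-normal with mean 2×10^6 and CV 0.2; counts are
  negative-binomial with dispersion 0.05 (Poisson when dispersion ≈ 0).
  TPM/FPKM columns are filled by the package's own quantification, so files
  are internally consistent.
* Determinism: one RNG stream, documented draw order; a (config, seed) pair
  regenerates files bit-exactly (floats are written in shortest round-trip
  form).

Defining behavior (verified per seed on seeds 1–10, asserted in the
acceptance tests): contaminated models show median CV ordering TPM > FPKM ≥
normalized counts and mean ICC_g(TPM) < ICC_g(normalized counts), both taken
over the four contaminated models; Euclidean-distance clustering leaves ≥ 1
model discordant for TPM and none for either count normalization; top-5
fraction spread is larger in contaminated than clean models; and with
contamination off, all measures are fully concordant and replicate-mean
normalized counts recover the true propensities at Spearman ρ > 0.95 per
model.  The orderings are asserted on contaminated-model aggregates rather
than per model: with 3 replicates and f drawn independently per replicate, a
contaminated model can draw a narrow f range and be indistinguishable from a
clean one, so per-model orderings are not stable properties of the design.

What the generator does *not* emulate — and what passing tests therefore do
not show: real tumor heterogeneity (correlated gene programs, cancer-type
structure; model effects here are i.i.d. per gene), mouse-read
contamination, isoform-level effects, GC/length biases, and batch effects.
Two known departures from real-data behavior: (1) the contamination shift is
common to all genes in log space, so 1−Pearson distances barely move and
Pearson-metric discordance stays 0 (real contaminated replicates also showed
correlation-metric discordance); (2) the shared shift inflates between-model
variance of TPM for every gene, so median ICC_m comes out slightly *higher*
for TPM than for normalized counts — the generator reproduces the CV, ICC_g
and Euclidean-clustering phenomenology but not the ICC_m ordering.  Absolute
CV levels (~0.23 at the default dispersion) are likewise benchmark
conditions, not estimates of any particular dataset.

## Numerical choices and degenerate inputs

* Pseudocount 1 and base 2 for all log transforms; double log-transform is
  rejected.
* Z-score: median-centered numerator, SD (n−1) about the mean, as
  conventionally printed; `sd_about="median"` is available since the
  combination is ambiguous; zero-SD genes get Z = 0 and are flagged.
* Degenerate inputs raise typed errors rather than propagating NaN:
  all-zero samples, positive counts with zero effective length, no
  all-positive reference gene (median-of-ratios), trim-exhausted gene sets
  (TMM), zero-variance samples (Pearson), all-identical matrices (ICC).
* Report TSVs are written at 3 decimals with a full-precision sidecar;
  reports are byte-deterministic for fixed inputs and options.

## Limitations

The pipeline is gene-level only; transcript-level files, read-level
simulation, and differential-expression analysis are out of scope.  The
discordance statistic treats the dendrogram as a hard partition hierarchy —
it does not measure *how far* a replicate strayed (the maximum-height table
partially covers this).  ICC confidence intervals and two-way ICC variants
(rater-effect models) are not implemented.
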