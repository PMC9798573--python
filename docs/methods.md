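# Methods

## Overview

`irkit` quantifies intron retention (IR) from spliced RNA-seq alignments and
tests for differential retention between two sample groups (typically tumour
vs adjacent normal tissue). It further screens gene expression for IR
correlates and condition-exclusive genes, and tests whether RNA-binding
protein (RBP) motifs are enriched around the splice sites of differentially
retained introns. All stages are testable without external data through a
ground-truth synthetic cohort generator.

## Intron reference

Introns are gaps between consecutive exons of a transcript, derived from a
GTF annotation under a union-consensus rule: identical introns contributed by
several isoforms are emitted once (recording the shortest flanking exons, a
conservative choice for flank sequence extraction), and introns that overlap
any exon of their own gene, any exon of another gene, or that are shared
verbatim between genes are dropped — retention cannot be attributed
unambiguously there. Coordinates are 0-based half-open internally; GTF input
(1-based inclusive) is converted on parsing and the BED output keeps the
0-based convention. Which transcript set should define introns in
multi-isoform genes is genuinely open; union-consensus was chosen because it
is deterministic and requires no expression-weighted isoform selection.

## Per-intron metrics

For each intron and sample, from primary alignments (duplicate, secondary
and supplementary reads are skipped by flag):

* **ID** (intron depth): median per-base read depth across the whole intron.
  The median is the standard mean-of-central-pair for even lengths. The
  whole intron is used rather than an edge-trimmed region; edge trimming is
  a tool-specific refinement the contract here does not include, and the
  difference is noted as a limitation below.
* **coverage**: fraction of intron positions with depth ≥ 1.
* **SL / SR**: junction reads linking the transcript-5′/3′ flanking exon to
  another exon of the same gene, counted from CIGAR N-gaps whose boundary
  coincides with the intron boundary and whose far end lands inside an
  annotated exon of the gene. On the minus strand the genomic-right counter
  is SL. A read whose gap matches the intron exactly evidences both flanks,
  so it increments **SE** (splice exact) and both SL and SR.
* **IR ratio** = ID / (ID + max(SL, SR)), defined as 0 when both terms are
  zero. It estimates the fraction of the gene's transcripts retaining the
  intron; taking the max of SL and SR is conservative against spurious
  one-sided junction support.

Depth counts reads, not fragments; with paired-end data, overlapping mates
would double-count, which is why the synthetic generator is single-end.

## Cohort filters and IR events

An intron is eligible for event counting when, across the cohort:

1. **balance**: 0.7 ≤ SL/SR ≤ 1.3 (inclusive; false when SR = 0) in ≥ 50% of
   samples — an empirical proxy for constitutive flanking exons. The
   aggregation of this per-sample window to a cohort decision follows the
   same "in ≥ 50% of samples" convention as the other filters.
2. **junction support**: (SL + SR) > 10 (strict) in ≥ 50% of samples.
3. **coverage**: coverage > 0.5 (strict) in ≥ 50% of samples.
4. **IR floor**: IR ratio > 0.05 (strict) in ≥ 50% of the samples of at
   least one group — a 5% inclusion rate is taken as the floor of
   biological relevance.

All "≥ 50%" boundaries are inclusive; all cut-offs are strict. Samples with
no junction evidence for an intron fail every per-sample predicate (missing
evidence is not passing evidence). An **IR event** is a filtered intron
with IR ratio > 0.1 (strict) in a given sample; the per-sample event count
is the cohort-level IR burden statistic. A read-depth QC retains samples
with at least 40 million aligned reads by default (configurable; synthetic
cohorts are orders of magnitude smaller and skip this gate).

Group labels are arbitrary factors; with more than two groups the IR floor
requires the 50% quorum within at least one designated group, which makes
the same code reusable for subtype cohorts.

## Differential retention

IR ratios are proportions, so group differences are modelled with a beta
likelihood: y ~ Beta(μφ, (1−μ)φ) with logit(μ) = β₀ + β₁·group and constant
precision φ. Boundary observations are first pulled inside the unit
interval with the standard squeeze (y·(n−1) + 0.5)/n, n = number of
samples. The MLE is found by BFGS on (β₀, β₁, log φ) with the analytic
score, starting from moment estimates (logit of group means; φ from the
pooled variance) and restarting once from a perturbed start on failure;
convergence is judged by the score norm because quasi-Newton optimizers
commonly stop with a "precision loss" status at points whose gradient is
already ~1e-6. The standard error of β₁ comes from the inverse observed
information (central-difference Hessian of the analytic score), and the
group effect is tested with a two-sided normal Wald statistic — the default
inference of standard beta-regression software, preferred here over a
likelihood-ratio test for comparability. Non-converged fits report p = 1
rather than being dropped, a conservative choice that cannot create false
positives. Benjamini–Hochberg adjustment (via statsmodels) controls the
FDR across introns.

An intron is called differentially retained when |ΔIR| > 0.1 (strict) and
BH q < 0.05, where ΔIR is the difference of *raw* group means of IR ratios
(cancer − normal), not model-fitted means — the effect threshold is defined
on the measurement scale. Fits are performed on filter-passing introns
only. Under the null (n = 20/group, φ = 20) the empirical Wald rejection at
α = 0.05 is ≈ 0.06 — the small-sample anti-conservatism expected of Wald
tests with an ML precision estimate; the BH layer keeps false calls near
zero in practice.

For designs with too few replicates for regression (e.g. two cell lines),
the Audic–Claverie test compares a count x in library N1 with y in N2 via
the exact conditional distribution P(Y=y|x) = r^y (x+y)! / (x! y!
(1+r)^{x+y+1}), r = N2/N1, summed in log space. The two-sided p doubles the
smaller inclusive tail, capped at 1. This definition is not exactly
exchangeable under (x, N1) ↔ (y, N2): the swapped inclusive tails differ by
precisely the probability atom at the observed count, so symmetry holds
only up to that atom (exactly, at x = y).

## Expression screens

Counts are normalized with median-of-ratios size factors (computed over
genes positive in all samples, rescaled to unit geometric mean).
Differential-expression *testing* is deliberately out of scope — practition-
ers run a dedicated NB-GLM tool for that — but the downstream logic that
consumes DE results is implemented:

* **log2 fold change** of mean normalized counts (pseudocount 1) and the
  mean-count > 10 gene pre-filter;
* **exclusive DE genes**: the reference condition's DE set minus the union
  of every other condition's set;
* **specificity z-score**: for a gene's per-condition log2 fold changes,
  z = (lfc_ref − mean) / sd with the n−1 denominator, mean and sd over all
  conditions including the reference (the reference's value is the scored
  quantity; excluding it is available behind a switch). Zero cross-condition
  sd yields z = 0 with a warning.
* **correlation screen**: Pearson r between log10(IR events + 1) and
  log10(normalized count + 1) per gene; the log10–log10 scale matches how
  such relationships are visualised and makes the association approximately
  linear. Zero-variance genes report r = 0 with a degeneracy flag. Top and
  bottom 5% selections use ceil(fraction·n) with gene-identifier
  tie-breaking for determinism.

## Motif enrichment at splice-site flanks

Each splice site contributes a 50-nt exonic and a 50-nt intronic window
(100 nt per splice-site neighbourhood, four regions per intron), always in
transcript orientation — RBP motifs bind RNA, so only the sense strand is
meaningful and minus-strand windows are reverse-complemented with their
tags swapped. Windows are clipped at feature boundaries and flagged when
truncated.

PWMs (MEME minimal or ATtRACT-style tab dialects; U ≡ T) are
pseudocount-regularized and scored as log2 odds against an i.i.d.
background. The hit threshold is calibrated per motif so that a random
background window reaches it with probability ≤ p_target (default 1e-4, a
conventional scanning stringency, configurable): the exact score
distribution is computed by dynamic programming over per-position scores
floored to 0.01-bit bins, and the threshold is the smallest mass-bearing
binned score whose upper tail is ≤ p_target, returned as the lower bin edge
(conservative by at most one bin). Flooring rather than rounding guarantees
a window scoring exactly at an atom is never excluded by discretization.

Per-region mean hit counts of differentially retained vs non-retained
introns are compared with a two-sample pooled-variance Student t test
(hits-per-sequence; a fraction-of-sequences binary mode is available). Two
constant equal groups give t = 0, p = 1; two constant but different groups
(pooled sd 0) are reported as a maximally significant degenerate case with
an explicit flag instead of a crash. BH q-values are added across
motif × region tests.

## Synthetic data generator

The generator emulates the *structure* of a tumour/normal cohort at desk
scale with exact ground truth:

* **genome/annotation**: one contig of i.i.d. uniform bases; each gene has
  one transcript of alternating exons (120 bp) and introns (60 bp), genes
  alternating strand, 100 bp intergenic gaps.
* **reads**: per intron and sample, a retention fraction π is drawn from
  Beta(mean θ_group, precision φ_sim = 30), the fragment count from
  Poisson(depth = 100 by default), and each fragment is unspliced with
  probability π. Unspliced fragments are single 75-nt match blocks that
  span the whole intron (start uniform over covering offsets), so the
  intron depth ID equals the unspliced fragment count *exactly* and the
  estimated IR ratio U/(U+S) has a closed-form binomial link to π — the
  property the consistency checks exploit. Spliced fragments carry an
  N-gap exactly matching the intron. Intron length is therefore
  constrained to read length − 2.
* **cohort**: 20 normal + 20 cancer samples by default; a random 20% of
  introns carry θ_cancer = θ_normal + 0.2 (baseline θ_normal = 0.1), the
  rest are null. Truth tables (per-intron θ and differential status,
  per-sample π) and a resolved design file are written beside the outputs.
* **expression**: negative-binomial counts (dispersion 0.1) with log-normal
  library-size variation (sd 0.3, mild but sufficient to exercise
  size-factor recovery) and planted genes whose log10 mean tracks the
  centred log10 IR event count with slope ±1.
* **motifs**: a consensus substring written at a uniform offset into a
  chosen flank region for a Bernoulli-rate subset of each intron class,
  reverse-complemented onto the genome for minus-strand introns.

Everything is a pure function of (design, seed).

What the generator does **not** emulate: isoform complexity and overlapping
genes, GC/positional bias, paired-end fragments, partial intron coverage
(unspliced reads always span the intron, so simulated coverage is 0 or 1),
edge-depth gradients, mapping ambiguity, and biological covariates (purity,
batch, subtype). Passing tests therefore demonstrate the correctness of the
counting, filtering, inference and scanning machinery under the stated
model — not robustness to alignment artefacts or confounding in real
cohorts.

## Numerical choices and degenerate inputs

* IR ratio 0/0 → 0; balance predicate false at SR = 0.
* Beta regression: squeeze before fitting; ≥ 3 observations per group
  required; p = 1 on non-convergence.
* Audic–Claverie: all tail mass in log space (gammaln), no factorial
  overflow.
* PWM DP: 0.01-bit bins, table capped at 2×10⁶ entries (error suggests
  coarser bins beyond that); −inf log-odds (zero probability without
  pseudocount) are rejected for calibration.
* Pearson degeneracy tested against a relative variance tolerance (1e-18 of
  the row scale) because centring a constant row leaves ~1e-16 residue.
* Tie-breaks in percentile selection are lexicographic on gene id.

## Default analysis sizes

The bundled analyses (test suite and the reproduction script) use cohorts
of 40–50 introns × 40 samples at depth 100–500 fragments per intron, 1000
introns for null-calibration and recovery studies, and 200 introns ×
100-sequence groups for motif enrichment. These sizes give stable
statistics (binomial/beta sampling error well below the decision
thresholds) while keeping any single analysis under a few minutes on one
core.

## Known limitations

* Whole-intron ID (no edge trimming) can differ from edge-trimmed depth
  metrics near splice sites in real data.
* Constant-precision beta regression; no covariates, no variable-φ, no LRT.
* The Wald test is mildly anti-conservative at n ≈ 20/group (see above).
* Single-end depth semantics; paired-end overlap handling is out of scope.
* i.i.d. background for PWM calibration; no higher-order background models
  or scan-wide q-values.
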