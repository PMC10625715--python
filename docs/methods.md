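# Methods

## Generative model

All estimation in this package inverts a single factorised law for the
probability that a sequenced base at a genomic A site reads as A
(persistent A) after enzymatic deamination:

```
pi = 1 − c · s · (1 − m_eff)
```

* `c` — sample-level conversion rate: the probability that the deaminase
  converts an accessible, unmethylated A. One value per sample.
* `s` — site accessibility in [0, 1]: the probability scale on which local
  secondary structure admits the enzyme. Estimated from a modification-free
  control that shares sequence context (and hence structure) with the
  treated sample.
* `m_eff` — effective methylation: `m` for the treated and FTO-minus
  samples, 0 for the in-vitro-transcribed (IVT) control, and `m(1 − e)` for
  an FTO-plus sample demethylated with efficiency `e`.

Observed A counts are binomial(n, pi) at depth n; the A-vs-G pair is
sufficient, and non-A/G observations are carried through I/O but excluded
from all model math. The factorisation itself is an assumption: conversion
requires enzyme competence, steric access, and the absence of the methyl
mark, taken as independent. It is the minimal model in which "exposed
methylation" (methylation × accessibility) is the naturally filterable
quantity, and every estimator below is its inverse in one regime.

## Estimators

**Conversion rate.** Pooled ratio `Σg / Σ(a+g)` over sites with coverage ≥
20 (default), resting on the assumption that the overwhelming majority of
A sites are unmethylated. The pooled ratio is the MLE under a shared-rate
binomial. Optional symmetric trimming of the per-site conversion
distribution (default 0) guards against methylated outliers when the
methylated fraction is not negligible. Note the estimand is effectively
`c · E[s]`: accessibility below 1 is indistinguishable from a lower
enzyme rate at the sample level. Both the treated and control samples
absorb the same factor, so downstream calling is unaffected; per-site
deviations of `s` from its mean are what the accessibility model captures.

**Apparent methylation.** With `s` absorbed into `c`, `pi = m + (1−m)(1−c)`
and the constrained MLE is the closed form
`clip((a/(a+g) − (1−c))/c, 0, 1)`. Clipping implements the boundary argmax;
no iterative optimisation is needed for the one-parameter case.

**Raw accessibility.** From the control (m = 0): `clip((g/(a+g))/c, 0, 1)`.

**Accessibility shrinkage.** Low-coverage raw estimates are noisy. An OLS
model predicts the *unclipped* ratio `(g/(a+g))/c` from the control A and
G counts plus an intercept (the A+G column is collinear and dropped),
trained on 2,000 randomly sampled sites; when fewer sites exist the model
trains on all of them and warns. The final estimate is
`clip(λ·predicted + (1−λ)·ratio, 0, 1)`. Two numerical choices matter:

* Regression and blending happen in unclipped space. Clipping at 1 before
  regression censors the sampling noise of near-boundary sites and tilts
  the fitted plane away from them; the unclipped ratio has mean `s` exactly.
* λ ∈ {0, 0.1, …, 1} is chosen by 10-fold cross-validation with a
  split-counts criterion: each held-out site's reads are divided
  binomially into two half-depth pseudo-replicates, and the blend built
  from half 1 plus the out-of-fold model prediction is scored against the
  ratio from half 2. Because the two halves are conditionally independent
  given the truth, this criterion equals the mean squared error to the true
  accessibility plus a λ-free noise term, so its argmin targets the right
  quantity. Scoring the blend against the same full-depth ratio it
  contains would always select λ = 0.

**Accessibility adjustment.** `true_m = clip(apparent_m / s, 0, 1)` when
`s > 0`, else missing; `exposed_m = true_m · s`, which is algebraically
`min(apparent_m, s)`. A fully blocked site has no defined methylation level
and an exposed level of 0.

**FTO joint fit.** With a demethylase control, accessibility cannot be
read off a modification-free sample; instead (m, s) are fitted jointly by
maximising the sum of the two binomial log-likelihoods with
`pi_minus = 1 − c₋ s (1−m)` and `pi_plus = 1 − c₊ s (1 − m(1−e))` over
[0, 1]². The demethylation efficiency `e` is fixed at the upper bound
estimated from 100%-methylated spike-in probes
(`e = clip(1 − m̂₊/m̂₋, 0, 1)`); using the bound makes the fitted
methylation conservative-low. Optimisation is a dense grid (step 0.005)
followed by bounded L-BFGS-B refinement accepted only if it improves the
grid optimum. When `e` is small the likelihood is nearly flat along an
`m·s` ridge; among near-ties the solution with maximal `s` (then minimal
`m`) is reported — the conservative "accessible but less methylated" call.
At `e = 0` the two samples share one likelihood and the model is
unidentifiable; this is an error.

**Read filter.** Before counting, reads in which more than 50% of the
covered reference-A positions are still read as A are discarded as poorly
processed by the enzyme. Reads covering no reference A have an undefined
(0/0) fraction and are kept — conservative for coverage.

## Site calling

Sites with ≥ 10 A+G counts in both samples (and not on the exclusion
list, e.g. known endogenous A-to-I editing positions) are evaluated. Each
gets a one-sided Fisher exact p-value for the alternative that the treated
sample's persistent-A proportion exceeds the control's — methylation can
only increase persistence, so the test is directional — followed by
Benjamini–Hochberg adjustment over the full evaluated family. A site
passes when q < 0.05 and exposed methylation ≥ 10%. Failed sites are
retained in the output with `passed=False` so that secondary analyses can
use the complete evaluated set. The BH family is defined as all evaluated
(coverage-passing, non-excluded) sites.

**Targeted quantification.** For a single locus read out by a Sanger trace
peak ratio or a small amplicon tally, the same background inversion
applies to the fraction directly: `clip((f_A − (1−c))/c, 0, 1)`.

## Downstream statistics

* **Motif classes**: DRACH iff the 5-mer centred on the site matches
  D ∈ {A,G,U}, R ∈ {A,G}, A, C, H ∈ {A,C,U}.
* **Calibration**: OLS of persistent-A percentage on designed m6A fraction
  across a probe dilution series; slope, intercept and r² reported.
* **Clustering**: neighbour gaps are successive within-transcript
  differences pooled over transcripts. The null resamples the same number
  of sites uniformly (optionally stratified to match the observed 5-mer
  frequencies exactly) from the pooled transcriptome-wide candidate list,
  10 repetitions by default. Sampling is transcriptome-wide rather than
  per-transcript, so transcript-level site density is part of what the
  test can detect. Gap analysis uses spliced (exon-concatenated)
  coordinates when an annotation is supplied, genomic positions otherwise.
* **Methylation load**: the sum of methylation levels over a transcript's
  called sites. Methylated transcripts are ranked by load (ties broken by
  transcript id) and split into high/medium/low tertiles by rank with
  remainders assigned top-down, plus a separate bin for methylation-free
  transcripts. Half-life comparisons use a one-tailed Wilcoxon rank-sum
  test against the unmethylated bin under the alternative that methylated
  transcripts decay faster. Half-lives are consumed from a precomputed
  table; estimating them from decay time courses is out of scope.
* **Spike-in dosing**: `y = d·v·c/t` attomole per µg of total RNA.

## Simulator

The simulator is first-class, tested code that defines the study
conditions for every downstream check. Defaults:

* conversion rates 0.99 for both treated and control samples — the rate a
  well-behaved hyperactive deaminase reaches;
* accessibility: 92% of sites drawn uniform(0.9, 1), the remainder
  uniform(0.2, 0.9) — 92% of sites at accessibility ≥ 0.9 with a modest
  structured tail;
* methylation of true m6A sites uniform(0, 1) — methylation levels in
  vivo are spread roughly evenly across stoichiometries;
* 85% of planted m6A sites have their 5-mer context overwritten with a
  random DRACH motif (minimum 5 nt separation so contexts cannot collide),
  the rest with a random non-DRACH A-centred 5-mer;
* coverage negative-binomial with mean 50 and dispersion 5; fragment
  length 150 nt for read-level simulation;
* FTO demethylation efficiency 0.9;
* 0.2% of background A sites carry endogenous A-to-I editing with a level
  drawn uniform(0.3, 0.9), applied as a persistent G excess in *every*
  sample role (editing precedes any enzymatic treatment), so callers see
  edited sites as hyper-converted rather than methylated.

Every generator is deterministic under the config seed; count tables,
read sets and probe sets use separate seed streams so adding one output
does not perturb another.

What the simulator does *not* emulate: sequencing error and base quality,
UMI collisions, alignment artifacts and multimapping, transcript-level
expression variation within a sample, strand-mixture libraries (simulated
transcripts are plus-strand), and covariation between accessibility and
motif. Passing tests therefore demonstrate correctness of the estimators
and calling logic under the stated binomial model, not robustness to
upstream artifacts — those are the province of the alignment and
deduplication tools whose outputs this package ingests.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen to keep the whole
suite fast while leaving the statistical checks well-powered: ~10,000
sites for null-calibration (FDR) runs, 2,000 sites per stoichiometry level
for recovery, 50–300 random instances for oracle-equivalence checks, and
10 permutation repetitions (the default) for clustering. The joint-fit
grid step is 0.005; the MLE oracle grid step is 1e-5 with agreement
required to 1e-4. The uniform-placement calibration check for the
clustering test draws densely (2,000 of 12,000 candidates) so the median
gap concentrates and the bracketing property is stable across seeds.

## Known limitations

* Stoichiometry estimates are noisy below ~25% methylation and at sites of
  low accessibility; the exposed-methylation filter removes most but a
  low-stoichiometry site on a poorly accessible position can be missed.
* The sample conversion rate absorbs mean accessibility (see above); `c`
  and `E[s]` are not separately identifiable from bulk counts.
* The shrinkage model is linear in (a, g); strongly non-linear
  coverage–accessibility relationships would be captured only partially.
* The FTO path inherits any error in the spike-in-derived efficiency
  bound; underestimating `e` biases methylation estimates downward.
* Transcriptome-scale analyses (per-transcript expression, metagene
  profiles, peak-level comparisons) are out of scope.
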