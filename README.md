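# etamseq

Detection and quantification of *N*6-methyladenosine (m6A) from global
A-to-I deamination sequencing.

## The problem

Hyperactive adenosine deaminases convert nearly every accessible,
unmethylated adenosine in RNA to inosine, which reverse-transcribes and
sequences as G. m6A resists deamination, so after treatment a methylated
position shows up as *persistent A*. Reading methylation stoichiometry out
of A/G counts requires untangling three confounded quantities:

* the sample-level conversion rate **c** — the probability that the enzyme
  deaminates an accessible unmethylated A;
* the per-site accessibility **s** ∈ [0, 1] — secondary structure can
  shield an A from the enzyme (0 = fully blocked, 1 = fully accessible),
  mimicking methylation;
* the methylation level **m** — the quantity of interest.

This package implements the statistical core of that readout for
epitranscriptomics researchers working with deamination-based m6A
sequencing data: count-table ingestion, the estimators, site calling,
probe calibration, and downstream statistics, together with a simulator
that generates all inputs with known truth.

## The model

The persistent-A probability at a site is

```
pi = 1 − c · s · (1 − m)
```

and observed A counts are binomial(n, pi) at sequencing depth n. The
estimators invert this law:

* **Conversion rate**: pooled G fraction over the bulk of A sites
  (most A sites are unmethylated), with optional symmetric trimming.
* **Apparent methylation** (treated sample, s absorbed):
  `m̂ = clip((a/(a+g) − (1−c)) / c, 0, 1)` — the closed-form constrained
  binomial MLE.
* **Accessibility** (modification-free IVT control, m = 0):
  `ŝ = clip((g/(a+g)) / c, 0, 1)`, then shrunk toward an OLS prediction
  from the control counts (λ chosen by 10-fold cross-validation on 2,000
  randomly sampled sites) to reduce low-coverage noise.
* **True and exposed methylation**: `true_m = clip(m̂ / ŝ, 0, 1)`,
  `exposed_m = true_m · ŝ`.
* **FTO mode**: with a demethylase-treated control instead of IVT, (m, s)
  are jointly maximum-likelihood fitted from the untreated/treated pair,
  using the demethylation efficiency bound `e` estimated from fully
  methylated spike-in probes.

A site is called m6A when it has ≥ 10 A+G counts in both samples, passes a
one-sided Fisher exact test at Benjamini–Hochberg FDR < 0.05, and shows an
exposed methylation level ≥ 10%.

## Worked example

Simulate a transcriptome with known truth and call sites:

```python
from etamseq import *
from etamseq.model import CallParams

config = SimConfig(seed=42, n_transcripts=30, transcript_length=1000,
                   n_m6a_sites=150, coverage_distribution=("nbinom", 80, 5))
sequences, truth = simulate_transcriptome(config)
treated = simulate_counts(truth, config, "treated")
ivt = simulate_counts(truth, config, "ivt")
treated.set_conversion_rate(estimate_conversion_rate(treated))
ivt.set_conversion_rate(estimate_conversion_rate(ivt))
calls = call_sites(treated, ivt, params=CallParams(), reference=sequences, seed=0)
```

This prints (via the summary statements in the example script):

```
conversion rates: treated 0.8985, IVT 0.9070
evaluated 7613 sites, called 109 m6A sites
DRACH fraction of called sites: 86.24%
example call: tx15:554:+ true_m=1.00 accessibility=1.00 q=3.11e-18
```

The pooled conversion-rate estimate (≈ 0.90) is the product of the
enzyme's conversion rate (0.99 in this simulation) and the mean site
accessibility; both samples share it, so calling and quantification are
unaffected. Of the called sites, ~86% sit in DRACH motifs
(D ∈ {A,G,U}, R ∈ {A,G}, then A, C, H ∈ {A,C,U}), matching the 85%
DRACH placement used by the generator. The example call is a fully
methylated, fully accessible site with an FDR-adjusted q-value of 3×10⁻¹⁸.

The same stages are scriptable from the shell:

```
etam simulate -c sim.json -o simdir
etam call --treated simdir/treated.tsv --control simdir/ivt.tsv \
          --fasta simdir/reference.fa --out calls.tsv --bed calls.bed
etam annotate --calls calls.tsv --out report.json
etam quantify-site --a-fraction 0.8 --rate 0.99   # -> 0.797980
```

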