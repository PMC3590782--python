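# Methods

## Scope and model

`itraqstat` analyses isobaric-label (iTRAQ 4-plex) shotgun-proteomics
experiments at the level of the PSM table: one row per peptide-spectrum
match carrying a protein accession, replicate coordinates and the four
reporter-ion intensities (channels 114-117). The experimental design it
targets has two nested levels of replication:

* a **workflow replicate** repeats the entire pipeline - immunodepletion,
  digestion, labeling, SCX fractionation, LC-MS/MS - from a fresh plasma
  aliquot; it is the proxy for biological replication;
* a **technical replicate** is one cumulative LC-MS/MS analysis of all
  SCX fractions within a workflow replicate.

All quantification is relative: peptide ratios are reporter-intensity
quotients against a reference channel (default 114), and a protein's
ratio in a technical replicate is the **median** of its peptide ratios.
Medians are permutation-invariant and scale-equivariant, and for odd
peptide counts commute with reference swapping (the reciprocal map is
monotone); for even counts we use the arithmetic mean of the two central
values, the standard convention.

### Filters

Identification and quantitation use separate spectral-count (SC)
filters, both defaulting to 2:

* identified in a workflow replicate ⇔ ≥ 2 PSMs pooled over its
  technical replicates, fractions and confidence tiers;
* quantifiable in a technical replicate ⇔ ≥ 2 PSMs within that run.

The second implies the first. A PSM with a zero/missing reference
intensity is excluded from ratios but still counts toward SC: zero means
"reporter not usable", not "protein not seen".

### Variance decomposition

Within a workflow replicate a protein's channel ratio is the mean of its
technical-replicate ratios. The per-protein **workflow CV** (sample SD /
mean, `ddof=1`) of those per-workflow values, averaged over proteins
quantified in ≥ 2 workflow replicates and over the three non-reference
channels, is the scalar `S_b` (total workflow-to-workflow variation).
The **technical CV** across runs within a workflow, averaged over
proteins quantified in ≥ 2 runs, is `S_t`. Quantile statements
("q% of proteins have CV < x") support both linear interpolation
(default) and nearest-rank conventions, since published summaries rarely
say which they used.

At n = 3 replicates the sample SD underestimates the true σ by the
factor c4(3) ≈ 0.886, so mean-CV estimates sit ~11% below the
generating CV; we deliberately report the raw (uncorrected) estimator,
which is what spreadsheet-based workflows compute. Tests that check the
variance-combination law therefore compare on the CV² scale, where the
sample variance is unbiased.

### Per-protein ANOVA

Consistency of a protein's ratio across workflow replicates is tested by
one-way fixed-effects ANOVA with workflow replicate as the factor and
technical-replicate ratios as observations (≥ 2 workflow replicates each
with ≥ 2 observations; scipy's `f_oneway` under the hood). The protein
is "consistent" iff P ≥ α (default 0.05). Degenerate inputs with zero
within-group variance get P = 1 when group means are equal and P = 0
otherwise, logged. Raw ratios are the default observation scale; a
`log2` mode is provided and recommended whenever ratios stray far from 1
(log-normal multiplicative noise is then closer to the F-test's
normality assumption). With ratios near 1 and CVs ≲ 0.1 the raw-scale
test is calibrated to within Monte-Carlo error (the suite verifies a
~5% type-I rate on null simulations). No multiple-testing correction is
applied; the per-protein calls are descriptive.

Note that with real between-workflow variation (`S_b > 0`) every protein
violates the ANOVA null, so the "consistent" fraction is a descriptive
measure of effect size relative to within-workflow noise, not an error
rate.

### Power planning

For a two-group comparison with `n` biological replicates per group and
`m` technical replicates each, the detectable fold-change cutoff is

    F = sqrt(C) * S / sqrt(n) + 1,      S = sqrt(S_b^2 + S_t^2 / m),

with inverse `n = C * S^2 / (F-1)^2`. Two choices of the coefficient
`C = 2(Z+T)^2` are implemented:

* `approximate` (default): C fixed at 20, i.e. sqrt(C) = 4.47, the
  rounded constant traditionally quoted for power 0.8 / α 0.05;
* `exact_quantiles`: C from the standard-normal quantiles themselves,
  two-sided α assumed; at power 0.8 / α 0.05, C = 2(0.8416+1.9600)² ≈
  15.70. The ≈25% discrepancy with the fixed constant is real and is
  carried in the curve output (`coefficient` column) rather than hidden.

The two functions are exact algebraic inverses before integer handling.
Required `n` is ceiled and clamped to a configurable minimum of 2 - a
group needs two members to have a variance - which is how statements
like "two replicates suffice for a 2.0-fold cutoff" arise from raw
formula values below 1. With default variances the cutoff at n = 10,
m = 1 is F ≈ 1.267, i.e. 1.3 at one decimal.

## Synthetic data generator

The generator emulates the reporter-summary level of the design: it
produces PSM tables, not spectra (no m/z peaks, isotope impurity or
ratio compression). Defaults are the study conditions: 2000 proteins,
4 channels mixed 1:1:1:1 (`channel_fold_changes = (1,1,1)`), 3 workflow
× 3 technical replicates, 13 fractions, `s_b = 0.16`, `s_t = 0.10`,
80% per-replicate detection.

Structure, per protein:

* expected SC per run drawn log-uniformly over `10^0.3..10^2.3`
  (≈ 2-200), counts per run negative-binomial (dispersion 4) - plasma
  abundances span orders of magnitude and counts are overdispersed;
* reference-channel base intensity log-uniform over `1e4..1e7`, with a
  per-PSM log-normal scale (σ_log = 1) shared by all four channels
  (peptide ionization efficiency; cancels in ratios);
* multiplicative log-normal noise at three levels: biological (one
  factor per protein × workflow replicate × channel), technical (per
  run × channel) and spectrum-level (`s_psm`, per PSM × channel,
  default 0.10). Each level's per-channel log-SD is
  `sqrt(ln(1+s²)/2)` so that the *ratio* of two channels has linear CV
  exactly `s` - CV dials are on the scale the statistics measure. With
  every dial at 0 the generated ratios equal the configured fold
  changes exactly (bitwise).
* detection per workflow replicate is Bernoulli(`detection_prob`),
  optionally coupled to log-abundance (`detection_abundance_slope`) so
  dropout concentrates in low-count proteins, reproducing partial
  replicate-overlap (Venn) structure.

Spectrum-level noise is what creates the CV-versus-spectral-count
trend: a protein quantified from k PSMs carries a median-of-k residual
of order `s_psm/sqrt(k)` on top of `s_t`. At the default `s_psm = 0.10`
this inflates recovered `S_t` by under 0.01, keeping parameter recovery
within its tolerance, while still giving low-SC proteins visibly higher
CVs; property tests that need a strong trend or dropout-CV coupling use
larger `s_psm` and a positive detection slope, which is where those
phenomena live in real data.

Determinism: one global integer seed; a per-protein sub-stream is
spawned from it (`numpy` `SeedSequence.spawn`), so the same seed yields
a byte-identical table.

What the generator does **not** model - and hence what passing tests do
not show about real data: shared/razor peptides and protein inference,
isotope-purity cross-talk and ratio compression, run-to-run retention
drift, intensity-dependent (heteroscedastic-in-intensity) noise floors,
and any real biological covariance between the four samples. Recovery of
`s_b`/`s_t` here validates the estimators, not the instrument.

## Pipeline sizes and numerical choices

The shipped defaults (2000 proteins, ≈ 600k PSMs) run the full
simulate → quantify → stats → power → coverage chain in well under a
minute; calibration-style checks use 5000 proteins. Quantiles default to
linear interpolation; CV estimators use `ddof=1` throughout; TSV output
prints floats at full round-trip precision. The pipeline manifest
records version, seed, all parameters and per-stage row counts, and
reruns with the same config and seed are byte-identical.

## Known limitations

* Accession comparison in the coverage module is literal string
  matching; cross-namespace comparisons (UniProt vs IPI vs gene symbol)
  need external mapping first.
* Peptide ratios are computed per spectrum; summing spectra per peptide
  sequence before ratioing is a plausible alternative some search
  engines use and is not implemented.
* The ANOVA treats technical-replicate ratios as independent
  observations; a mixed model would be more faithful when technical
  replicates share fraction-level artifacts.
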