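# Methods

`methaudit` implements a desk-scale specificity audit for CRISPR/dCas9-DNMT3A
("d3A") targeted DNA methylation. The scientific question it operationalises:
after directing a methyltransferase to one CpG island with a handful of
sgRNAs, is the induced methylation, and its downstream transcriptional
effect, confined to the intended gene? The audit triangulates three
independent data types — clonal bisulfite sequencing, array-style genome-wide
methylation, and bulk RNA expression — and intersects them with an exhaustive
guide off-target search.

## The simulated study

No public data accompany the design this package models, so the
`simulate` module is a first-class component that generates every input with
the statistical structure the analysis assumes. The default configuration
encodes the study conditions:

| parameter | default | meaning |
|---|---|---|
| `island_span` | 762 bp | CpG island length (promoter islands of this size are typical) |
| `n_cpg_sites` | 96 | indexed CpG dinucleotides, numbered 1..96 in 5'→3' order |
| `n_guides` | 4 | sgRNAs; one in the first assay region, three in the second |
| `deposition_radius` | 20 bp | methylation deposition kernel half-width around a protospacer |
| `upstream_bias` | 0.9 | fraction of kernel weight on the guide's 5'-upstream side |
| `n_target_probes` | 3 | hyper-methylated array probes in the target gene |
| `delta_m_target` | +3 | planted treated-minus-control M-value shift |
| `baseline_meth_prob` | 0.11 | control per-site methylation probability |
| `beta_noise_sd` | 0.5 | per-sample Gaussian noise SD on the M scale |
| `n_samples_per_group` | 3 | array samples per arm (control "scRNA" vs treated "sgRNA") |
| `target_gene_log2fc` | −2 | planted knockdown of the target gene |
| `incongruent_log2fc` | +2 | planted expression *increase* of the incongruent gene |
| `nb_dispersion` | 0.1 | common negative-binomial dispersion of the count matrix |
| `n_rna_samples_per_group` | 5 | RNA samples per arm |
| `n_clones_per_region` | 50 | bisulfite clones per amplicon region |

Rationale for the less obvious choices:

- **Baseline 0.11.** The logit2 map takes beta 0.111 to M = −3, so control
  island probes sit near M ≈ −3 and planted probes (ΔM = +3) land near
  M ≈ 0 — an unmethylated island that becomes half-methylated, the regime
  the classifier's "control M < −1, treated M > −1" criteria describe.
- **Noise on the M scale.** M-values are the analysis currency and are
  unbounded; adding noise there and mapping back to (0,1) avoids boundary
  pile-up that beta-scale noise would create.
- **Pinned planted effects.** The designated target probes (and the planted
  incongruent probes) are emitted at control M + `delta_m_target` exactly,
  rather than through the treated site-probability profile, so the planted
  group difference is centred at the configured effect. Likewise both
  planted expression effects share the pinned base mean (500) and a |log2FC|
  of 2: planted constructs are sized so the design (n = 5 vs 5, BH at 0.05)
  detects them with high probability; an underpowered plant would conflate
  generator noise with pipeline failure.
- **Guide anchoring.** Each guide is placed so that at least one indexed CpG
  lies 15–20 bp on its 5'-upstream side. Without such a witness site near
  the kernel edge, the deposition radius would not be identifiable from
  clone composites.
- **Labelled substreams.** Every output object draws from
  `default_rng([seed, crc32(label)])`, so requesting more clones never
  perturbs the beta matrix; identical configurations are byte-identical.
- **Batch factor.** The sample sheet carries an alternating a/b batch label
  that the models ignore by default (`include_batch` adds an additive
  covariate); the emulated design ran two array batches but clustered by
  group regardless.

What the generator does *not* emulate: probe-level technology artefacts
(dye bias, type I/II probe chemistry, SNP-overlapping probes), read-level
sequencing error, mean-dispersion trends across genes, or correlated probes
within a locus beyond the shared footprint signal. Passing tests therefore
demonstrate the correctness and calibration of the analysis rules under the
assumed emission models, not robustness to those real-data artefacts.

## Bisulfite clone analysis

In-silico conversion deaminates every cytosine outside a CpG context with
probability `conversion_rate` and protects methylated CpG cytosines;
`conversion_rate = 1` is deterministic. Calling compares a clone read to the
coordinate-matched amplicon reference at indexed CpG positions only: C →
methylated, T → unmethylated, anything else → ambiguous (dropped from
denominators; a neutral stand-in for manual chromatogram review). Reads are
not gap-aligned — amplicon clones are assumed Sanger-clean, and a length
mismatch is an error, not an alignment problem. Conversion QC is the
fraction of non-CpG reference cytosines read as T.

The composite row is the per-site methylated fraction over informative
calls; a site with zero informative calls is missing, not 0. Region
summaries restrict to inclusive CpG-number ranges (DMR1 = 25–50,
DMR2 = 73–90, MSP = 76–87, core promoter = 50–62, enhancer = 82–87; assay
regions flanked by sites 22/57 and 72/96), rescaled proportionally when the
island is configured with a different site count.

Asymmetry is measured in bases (not CpG-index units) from the nearest
protospacer edge, negative on the guide's 5'-upstream side; "upstream" is
the 5' side of the protospacer on the strand the guide binds. Sites at or
above `frequency_floor` (default 0.5 — a majority-of-clones notion of
"methylated") qualify; the radius estimate is the largest absolute distance
among qualifying sites. Measuring from the protospacer edge rather than the
PAM is a convention choice, noted here because a 3-bp shift matters at
20-bp scales. With no qualifying site the report is flagged undefined
rather than zero.

## Array methylome arm

Betas are clipped to [1e-3, 1−1e-3] before the logit2 transform to keep
M finite. The per-probe SD (all samples pooled, ddof = 1) is the single
statistic behind both the unsupervised variance pre-filter and criterion (3)
of the classifier. "k SDs above the average M-value SD" is read as
mean(SD) + k·SD(SD) over the per-probe SD distribution — the offset rule —
with the alternative reading k·mean(SD) available as `sd_rule="scaled"`.
Comparisons are strict at every threshold.

The supervised test fits, per probe, an ordinary linear model (intercept +
treated indicator, optionally + batch) and moderates the residual variances
empirically: hyperparameters (d0, s0²) come from closed-form moment matching
of log s² via digamma/trigamma inversion, with d0 = ∞ (full shrinkage, and
a normal reference) when the observed spread of log s² does not exceed the
chi-square contribution; d0 is capped at 1e6. The moderated t refers to a
t distribution on d + d0 degrees of freedom. `d0_override=0` reproduces the
classical two-sample t exactly; the test suite verifies agreement with the
R reference implementation of this moderation (limma) to ~1e-8 on a shared
fixture. Multiple testing uses Benjamini–Hochberg throughout.

A probe is an on/off-target *candidate* iff all five criteria hold: BH-
adjusted p < 0.05; CpG-island annotation; ΔM above the offset rule at
multiplier 2.0; control mean M < −1; treated mean M > −1. Candidates
collapse to unique genes (empty labels conserved under "intergenic"); genes
with candidate probes in both directions are marked "mixed" and never
on-target.

The orchestrated pipeline applies the supervised test to the variance-kept
subset (multiplier 2.5), mirroring the sequential unsupervised-then-
supervised design it emulates; the standalone `classify_probes` operates on
whatever matrix it is given, with the SD statistics of the full matrix
passed in (`sd_stats`) so both stages share one SD vector.

## Expression arm

Median-of-ratios size factors (reference set: genes positive in every
sample; factors are defined only up to a common scale — ratios between
samples are the invariant quantity). Per-gene dispersion is method-of-
moments on normalized counts, α = (s² − μ)/μ² pooled across groups by
residual df, floored at 1e-8 (the Poisson limit) and capped at 10. Moment
estimates below the cross-gene median are raised to the median: at n = 5
per group the per-gene estimate is noisy, and its downward excursions
directly inflate Wald statistics (measured type-I ≈ 0.087 without the
clip, ≈ 0.046 with it, at 2000 null genes, α = 0.1, n = 5 vs 5). No
mean-dispersion trend is fitted and no fold-change shrinkage is applied —
the intersection consumes only significance and sign, and the simple
estimator is auditable against brute force; this is a deliberate divergence
from full DESeq2-style machinery, and equivalence with that tool is not
claimed.

The two-group NB GLM (log link, size-factor offsets) is fitted by
iteratively reweighted scoring, vectorised across genes (linear predictor
clipped to ±30; convergence at 1e-8; 50 iterations). The Wald statistic
refers to the standard normal, the referenced tool's convention. All-zero
genes are untestable; non-converged genes are flagged with missing p-values
and excluded from the BH family, never silently dropped.

## Guide off-target search

Exhaustive enumeration on both strands of every 20-mer within Hamming
distance ≤ `max_mismatch` (default 3; no seed-region weighting) of a spacer
with an IUPAC PAM (default NGG) immediately 3'. PAM bases never count as
mismatches; genomic N never matches a spacer or PAM base. Reverse-strand
hits are reported in forward coordinates with spacer-indexed mismatch
positions. The implementation is vectorised over sliding windows, but its
contract is equality with a naive position-by-position scan, which the
tests enforce. Probe proximity is the minimal base separation between the
probe coordinate and the protospacer interval (0 inside), kept iff
≤ `window` (default 1000, closed bound), same chromosome required.

## Integration

Per gene: `on_target` iff candidate hyper/hypo-methylation, significant DE,
congruent direction, and a guide hit within the window of a *supporting
candidate probe* (not the gene body); `off_target_candidate` if the same
molecular evidence lacks a proximal guide site; `incongruent` if both
assays are significant but move the same way (methylation up with
expression up); then `methylation_only`, `expression_only`, `unaffected`.
Congruence is directional: hyper-methylation with decreased expression is
the canonical case; hypo-methylation with increased expression is also
treated as congruent but flagged separately (`congruent_direction`). Every
gene in either evidence table receives exactly one label; the JSON report
records per-stage counts (conserving probe totals across filters) and every
threshold used, and is byte-reproducible for a fixed configuration.

## Problem sizes and numerical notes

Default demo: 2,000 probes × 6 samples, 500 genes × 10 samples, 20-kb
genome, 50 clones per region — sizes chosen so a full audit runs in well
under a second while every statistical regime (BH families, variance-rule
tails, kernel recovery) is exercised; the probe-recovery studies use
20,000 probes. Calibration studies use 2,000 null features. Monte-Carlo
assertions in the tests use joint (Bonferroni-split) binomial envelopes and
bounds derived from the estimators' sampling distributions; with the
default conditions the end-to-end label set is recovered in ≥ 29/30 seeds,
the residual misses being sampling noise of the DE call at the planted
effect sizes, not classifier failures.

## Known limitations

- Beta emission assumes one methylation level per probe footprint; real
  arrays mix cell populations and probe chemistries.
- The NB model uses a common design across genes and no covariates beyond
  group (and optional batch for the methylome arm only).
- The guide search models mismatches only — no bulges, no cutting-
  efficiency scores — and is not tuned for genome-scale human searches.
- Clone reads must be indel-free and coordinate-matched; there is no
  chromatogram parsing.
- With multiple guides in one region the deposition radius is not
  identifiable from composites (overlapping kernels), which the region-2
  asymmetry report reproduces; radius estimates are meaningful only for
  isolated guides.
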