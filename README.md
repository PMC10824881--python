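# methaudit

Specificity audit for CRISPR/dCas9-DNMT3A targeted DNA methylation.

Fusing catalytically dead Cas9 to the DNMT3A methyltransferase domain
("d3A") lets a handful of sgRNAs deposit CpG methylation on a chosen
promoter — e.g. silencing *MGMT* to re-sensitise glioma cells to
temozolomide — without cutting DNA. The safety question is specificity:
did methylation, and its transcriptional consequence, land anywhere else?
`methaudit` is a reusable, tested pipeline for that audit, aimed at
epigenome-editing groups who have (or want to prototype against) three
complementary readouts:

1. **Clonal bisulfite sequencing** of the target CpG island: per-clone
   methylation calls, lollipop/composite summaries, region statistics
   (DMR1/DMR2/MSP/promoter/enhancer), and guide-relative asymmetry — how
   far from the protospacer does deposited methylation reach, and is it
   biased to the 5'-upstream side?
2. **Methylation array statistics** on M-values, M = log2(β/(1−β)):
   per-probe SD variance filtering (mean(SD) + k·SD(SD)), a two-group
   linear model with empirical-Bayes variance moderation
   (s̃² = (d₀s₀² + d s²)/(d₀ + d), moderated t on d₀ + d df, BH-adjusted),
   and the four-criterion candidate classifier: p-adj < 0.05, CpG-island
   probe, ΔM above the 2-SD rule, control mean M < −1 (with treated mean
   M > −1).
3. **RNA differential expression**: median-of-ratios size factors,
   method-of-moments NB dispersion, and a per-gene negative-binomial Wald
   test (log2FC / SE against the standard normal).

A PAM-anchored exhaustive mismatch search (NGG, both strands, budget ≤ 3 by
default) enumerates candidate guide binding sites; hits within 1000 bases
of a candidate probe constitute proximity evidence. The three-way
intersection labels every gene `on_target`, `off_target_candidate`,
`incongruent` (both assays significant but moving the same way —
methylation up *and* expression up), `methylation_only`,
`expression_only`, or `unaffected`.

Because no public dataset accompanies the emulated design, the package
ships a first-class synthetic-data generator (`methaudit.simulate`) that
produces every input — toy genome with an indexed 96-site CpG island,
planted protospacers and decoy near-matches, probe manifest, beta and
count matrices, bisulfite clone reads — from a single seed, with
byte-identical reruns. Real data enter through the same plain-text
formats (TSV matrices, FASTA, BED-like manifests).

## Worked example

```sh
methaudit run --seed 7 --out demo/
```

prints

```
on-target genes: ['MGMT']
report written to demo/report.json
```

and `demo/report.json` contains (excerpt):

```json
"labels": {
  "on_target": 1, "off_target_candidate": 0, "incongruent": 1,
  "methylation_only": 0, "expression_only": 0, "unaffected": 498
},
"stages": {
  "probes_total": 2000, "probes_kept_variance": 18,
  "probes_candidate": 4, "candidate_genes": 2,
  "genes_de_significant": 2, "guide_hits": 12, "proximity_records": 60
},
"clones": {
  "region1": {"guide": "sg4", "upstream_fraction": 1.0,
              "radius_estimate_bp": 18.0}
}
```

Reading: of 2,000 probes, 18 survive the 2.5-SD variance filter; 4 pass
all classifier criteria, collapsing to 2 genes. The simulated target gene
*MGMT* (3 supporting probes, knockdown log2FC ≈ −2, guide hit 0–5 bp from
a probe) is the single `on_target` call; the planted gene whose
methylation *and* expression both increased is labelled `incongruent` and
can never be on-target. Clone analysis of the first assay region finds
every majority-methylated CpG on the 5'-upstream side of sg4 within
≈ 20 bp — the deposition kernel the generator planted. In the multi-guide
second region the radius is not identifiable (overlapping kernels), which
the report reproduces.

Each stage is also exposed separately (`methaudit simulate / clones / dm /
de / guides`) and as library functions; see `docs/methods.md` for the
models, thresholds, and design choices.

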