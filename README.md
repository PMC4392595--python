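# chromdyn

Integrative chromatin-dynamics analysis for ChIP-seq and RNA-seq, built
around the question of how a chromatin remodeler (Brg1/Smarca4, the BAF
ATPase) shapes enhancer activation during mesoderm differentiation: which
distal regulatory elements gain H3K27ac as cells differentiate, which of
them depend on the remodeler for that gain, and what happens to
Polycomb-repressed (H3K27me3-marked) developmental genes when the remodeler
is removed.

The package is aimed at computational biologists who want a tested,
self-contained implementation of this analysis style — each stage is a
library function, a synthetic-data generator plants a known regulatory
landscape so every stage can be validated against ground truth, and a CLI
runs the whole pipeline end to end.

## What it computes

- **Peak calling** — an input-corrected Poisson model: sliding windows over
  binned coverage, local expectation
  `λ = max(λ_floor, input_window × lib_chip/lib_input)` with
  `λ_floor = lib_chip · window/genome`, upper-tail p-values
  `P(X ≥ k | λ)`, Benjamini–Hochberg correction across windows, and
  merging of significant windows. High-confidence regions are the
  intersection of biological replicates (every reported region is
  enriched in both).
- **Enhancer dynamics** — putative enhancers are H3K27ac regions >2.5 kb
  from every TSS; an enhancer is *static* if it shares ≥1 bp with a
  precursor-state (ESC) H3K27ac region and *activated* otherwise.
  Differential acetylation per enhancer is `log2((KO + c)/(ctrl + c))` on
  per-million-normalized density, with cohort medians (activated, static,
  remodeler-bound, unbound, near-downregulated-genes).
- **Super-enhancers** — ROSE-style stitching of distal peaks within
  12.5 kb, ranked by input-subtracted signal; the cutoff sits where the
  scaled rank-signal curve has tangent slope 1.
- **Expression** — RPKM (`count · 10⁹ / (library · exonic bp)`), an
  expression floor of 0.5 RPKM in at least one condition, differential
  expression at FDR ≤ 1% plus ≥2-fold change (overdispersion-aware Wald
  test by default; exact binomial split test as an option), induction
  classification (activated/repressed/static), and the overlap of
  remodeler-dependent genes with those classes.
- **Region statistics** — permutation overlap tests (chromosome- and
  length-preserving shuffles, add-one empirical p), exact hypergeometric
  enrichment, Pearson chi-squared, a paired rank test (Wilcoxon
  signed-rank with an exact convolution null for n ≤ 25), and PWM motif
  enrichment with Fisher tests and BH correction.
- **Density views** — anchored (TSS or midpoint) ±5 kb density matrices,
  ranked heatmap ordering, composite profiles, and a 2-means partition of
  genes by promoter H3K27me3 load (group I = Polycomb-high).
- **Synthetic data** — a toy genome with gene models, planted enhancers in
  three dynamics classes with a remodeler-dependence factor δ, Polycomb
  promoter domains that decay in the knockout, Poisson ChIP tracks with
  triangular peak kernels, and negative-binomial RNA-seq counts whose
  condition effects are tied to the enhancer truth.

## Worked example

```bash
chromdyn simulate --seed 1 --outdir demo
chromdyn integrate --seed 1 --outdir demo
chromdyn report --outdir demo
```

The report on the default synthetic landscape (seed 1) prints:

```
# Integrated chromatin-dynamics report

## Differential expression
- expressed genes: 600
- knockout: 66 down, 80 up (FDR <= 1%, fold >= 2)

## Remodeler-bound regions
- high-confidence regions (both replicates): 84
- genomic context: {'promoter': 0, 'exon': 2, 'intron': 3, 'intergenic': 79}
- replicate signal correlation r^2 = 0.982

## Enhancers
- putative distal enhancers: 196 (99 activated, 97 static)
- distal remodeler regions overlapping enhancers: 1.000 (permutation p = 0.0001)
- H3K27ac log2FC medians: all 0.011, activated -0.821, static 0.052, bound -0.836, unbound 0.050
- enhancer/expression log2FC correlation r = 0.763
- bound-enhancer enrichment near downregulated genes: hypergeometric p = 1.17e-27
- activated-vs-static remodeler occupancy: chi-squared p = 4.71e-14
- super-enhancers: 20

## Polycomb domains
- group I (high H3K27me3) genes among derepressed: 50
- control vs knockout H3K27me3 at group I promoters: paired rank p = 7.56e-10
```

Read: with the remodeler deleted, activated enhancers lose roughly half
their acetylation (median log2FC ≈ −0.8 under planted δ = 0.5) while static
enhancers are untouched; remodeler-bound regions sit almost entirely inside
predicted enhancers (the permutation p is at the add-one floor for 10,000
shuffles); acetylation changes at enhancers track expression changes of
their nearest genes; and Polycomb-marked derepressed genes lose H3K27me3 at
their promoters.

The same analyses are available as library calls; see
`chromdyn.pipeline.simulate_dataset` / `integrate` and the per-stage
modules (`peaks`, `enhancers`, `expression`, `density`, `stats`).

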