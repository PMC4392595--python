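# Methods

This note documents the models implemented in `chromdyn`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open (`[start, end)`, BED convention);
bedGraph output follows the same convention. Overlap between intervals
means sharing at least one base pair. Distance from an interval to a TSS
is measured edge-to-point: 0 if the TSS lies inside the interval,
otherwise the bp gap to the nearest edge. "Distal" is strict: an element
is promoter-proximal when its TSS distance is ≤ 2500 bp, distal when it
exceeds 2500 bp. Ties in nearest-gene assignment break to the
lexicographically smaller gene id, so every assignment is deterministic.
Genomic-context annotation (promoter > exon > intron > intergenic) is
assessed at the interval midpoint; proximity partitioning uses the edge
distance. The midpoint rule exists because context is a property of where
the bulk of a region sits, while promoter capture should be conservative.

Interval shuffling — the permutation-test null — re-places each interval
uniformly among all positions on its own chromosome where it fits outside
the exclusion set. The allowed-start segments are computed exactly, so
placement is a single draw (no rejection loop) and the per-chromosome
interval counts and the length multiset are preserved exactly. Keeping the
chromosome fixed is the conservative null: it preserves chromosome
composition of the query set.

## Peak calling

The caller tests fixed-width sliding windows (default 500 bp, step 25 bp)
of binned coverage (25 bp bins) against a local Poisson expectation
derived from the matched input track:

    λ_local = max(λ_floor, input_window_count × lib_chip / lib_input)
    λ_floor = lib_chip × window / genome_size

The floor prevents input dropouts from producing spuriously significant
windows; on a flat background it makes the caller conservative, which the
calibration study confirms (no windows at q ≤ 0.01 on background-only
tracks across 20 seeds). Raw p-values are the upper tail `P(X ≥ k |
λ_local)`; Benjamini–Hochberg correction runs across all tested windows.
Windows at q ≤ 0.01 are merged within 100 bp; each merged region reports
its summit (max-count bin), region-level counts and fold enrichment, and
the minimum window q inside it.

The 500 bp default window deserves a note: the synthetic enrichment
kernels span about 1 kb, and windows much wider than the signal footprint
pad called regions with flanking background. That padding dilutes
per-region density ratios toward zero — with 1 kb windows the measured
knockout/control acetylation log2FC at half-strength enhancers saturates
near −0.7 instead of −1. A window matched to the signal scale keeps
region density signal-dominated. Both window and step are configurable.

A duplicate cap (default 50 reads per exact position) is applied at the
read-position level before binning when reads, rather than binned
coverage, are the input.

High-confidence regions across biological replicates are the
*intersection*: every pair of replicate peaks sharing ≥1 bp contributes
the union span of the pair, and the result is merged. The operation is
commutative, and each output region overlaps at least one statistically
enriched peak in each replicate — the property the validation suite
checks exactly.

Replicate signal agreement is summarized as the Pearson correlation of
`log2(per-region normalized density + 1)`; the pseudocount of 1
normalized unit is stated here because nothing pins it down.

## Expression analysis

RPKM is `count × 10⁹ / (library × exonic_length)`. Genes below 0.5 RPKM
in every condition are excluded; the expression floor applies to at least
one condition.

Differential calls use the joint rule FDR ≤ 1% *and* |log2FC| ≥ 1, with
log2FC shrunken by a pseudocount of 0.5 reads per library. The default
per-gene test is a Wald test on the log rate ratio of pooled counts:

    var(log-ratio) ≈ 1/k_a + 1/k_b + 2·d̂/n_reps

where `d̂` is a global negative-binomial dispersion estimated from
within-condition replicate scatter by the method of moments. Each
adequately expressed gene (scaled mean ≥ 25) contributes
`(s² − mean)/mean²`; the estimator is their plain mean across genes and
conditions. Equal weighting matters: a total-sum ratio estimator is
dominated by the few most-expressed genes of a heavy-tailed expression
distribution and fluctuates enough to destabilize the FDR operating
point. An exact binomial split test (`Binomial(k_a+k_b,
lib_b/(lib_a+lib_b))`) and its normal approximation remain available;
the binomial version is exact under pure Poisson resampling and is kept
for closed-form oracle tests, but it ignores biological replicate
variance and overcalls when counts are overdispersed, so it is not the
default.

With two replicates and dispersion 0.05, a small number of truly null
genes realize ≥2-fold differences between the sampled condition means;
these are statistically indistinguishable from planted effects, which
places the planted-label FDR of the study near 0.02–0.06 depending on the
seed. This is a property of the study conditions, not of the test.

Induction classification maps the day-4-control-versus-day-2 differential
result to activated / repressed / static; the dependence analysis crosses
that classification with the knockout differential into a contingency
table, per-class fractions, and the induction-rank positions of
knockout-affected genes.

## Enhancer dynamics

Putative enhancers are the distal (>2.5 kb) partition of H3K27ac regions;
promoter-proximal regions are retained separately. Classification against
the precursor state uses ≥1 bp overlap with the ESC H3K27ac region set:
overlap ⇒ static, otherwise activated. An empty precursor set classifies
everything as activated, with a warning.

Per-enhancer density sums every normalized coverage bin fully or
partially inside the interval (partial bins counted whole — simple and
deterministic). Differential acetylation is `log2((KO + 1)/(ctrl + 1))`
in normalized units; cohort medians are reported for all enhancers,
activated, static, remodeler-bound, unbound, and enhancers nearest to
significantly downregulated genes. Medians are invariant to per-million
scaling and row order.

Super-enhancer stitching merges distal peaks within 12,500 bp (TSS
exclusion 2500 bp), ranks stitched regions by control signal minus input
signal, and places the cutoff where the rank-signal curve, with both axes
scaled to [0, 1], has tangent slope 1. For this convex increasing curve
the tangent point of a slope-1 support line is where `y − x` is minimal,
which is how it is computed; regions strictly above the cutoff signal are
flagged, making the flag monotone in signal by construction. Fewer than
three stitched regions, or an all-equal signal vector, leave the cutoff
undefined and raise an error.

## Density matrices and the group I/II partition

Density matrices cover ±5 kb around an anchor (region midpoint, or TSS
with minus-strand rows reversed so upstream is always left) in 100 bins
of 100 bp. Windows that extend past a chromosome end are zero-filled and
the row is flagged rather than dropped, keeping row sets aligned across
tracks. Matrix values are reads per bin per million; edge bins of each
window are pro-rated so the construction is exact and linear in the
track. Ranking sorts rows by the ranking track's row sums (stable,
descending, ties by region id). Composite profiles report columnwise mean
and median absolute deviation.

The group I/II split of derepressed genes clusters `log1p` H3K27me3 row
sums by one-dimensional 2-means with deterministic initialization at the
minimum and maximum; group I is the high-H3K27me3 cluster, and mean
promoter H3K27ac per group is reported as the cross-check (group I should
be low in H3K27ac). A rank-based variant exploits the partition's
invariance under monotone transforms for robustness checks. 2-means was
chosen over a fixed threshold because no threshold is canonical and the
deterministic-init version is exactly reproducible.

## Region-set statistics

The permutation overlap test measures the fraction of query intervals
overlapping a reference and compares it with shuffles that preserve
chromosome and length. The empirical p-value uses the add-one rule
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`, so it is never zero and is
valid at any `n_perm`. With few query intervals the overlap fraction is
coarse and tie mass makes the p-value conservative; calibration studies
therefore use ≥150 query intervals, where the p-value distribution is
uniform to KS precision. With no exclusions the null is sampled by a
vectorized fast path; exclusion sets fall back to the general exact
placement.

Hypergeometric enrichment is the exact upper tail; it is verified against
full combinatorial enumeration for every configuration with universe
≤ 30. Chi-squared is the Pearson statistic without continuity correction
(Yates correction available as a flag). The paired comparison of control
versus knockout densities is computed as the Wilcoxon signed-rank test —
the standard paired rank test — with zero differences dropped and
mid-ranks for ties; for n ≤ 25 the exact null of W⁺ is built by
convolution over the (doubled) ranks, which is arithmetically identical
to enumerating all 2ⁿ sign assignments, and above that a tie-corrected
normal approximation is used. Two-sided p is `2·min(P(W ≤ w), P(W ≥ w))`
capped at 1.

Motif enrichment takes user-supplied PWMs (JASPAR-format text via
Bio.motifs, or built from counts/consensus). A region is a hit when any
window on either strand scores at least 85% of the motif's maximal
log-odds score; hit rates in bound versus background regions are compared
by one-sided Fisher tests with BH correction across motifs, and the fold
is the hit-rate ratio. Proprietary motif databases are not bundled;
score-fraction thresholding replaces vendor-specific similarity scores.

## Synthetic data: what it emulates, and what it does not

The generator builds equal-sized chromosomes, gene models with 1–4 exons
(spans ≤ 8 kb, strand Bernoulli(0.5), TSS spacing enforced on whole gene
spans so that strand flips cannot violate it), and a planted regulatory
landscape:

- **Enhancers** in three classes — static (acetylated in precursor and
  differentiated states), activated (differentiated only), ESC-only
  (precursor only) — placed strictly >2.5 kb from every TSS, ≥2 kb apart,
  widths uniform in 400–1500 bp. Remodeler binding is drawn for 80% of
  activated and 20% of static enhancers by default, encoding the observed
  enrichment of remodeler occupancy at dynamically activated elements;
  precursor-only enhancers are never bound. Bound activated enhancers
  carry δ = 0.5: their knockout H3K27ac kernel is halved.
- **ChIP tracks** are per-bin Poisson draws over a uniform background
  plus triangular kernels (half-width 500 bp) at planted features. An
  enhancer's enrichment parameter is its mean fold over background across
  its own footprint; the default of 30 represents a strongly acetylated
  active enhancer, high enough that called-region density is dominated by
  signal rather than flanking background. Acetylated promoters (the
  more-expressed half of non-Polycomb genes) get fold-6 kernels that do
  not change in the knockout. Polycomb genes carry broad (±2 kb)
  fold-10 H3K27me3/Suz12 promoter domains whose knockout signal decays by
  half. Track totals are calibrated to the requested depth (1e6 by
  default); with a fixed total, knockout losses are redistributed into
  background, a deliberate emulation of fixed-depth sequencing
  (composition bias). Per-track seeds are spawned deterministically from
  the master seed and a fixed (mark, condition, replicate) table, so
  every track is reproducible and independent.
- **RNA-seq counts** are negative binomial (dispersion 0.05, typical of
  bulk RNA-seq) around lognormal baselines, with per-gene log2 effects:
  genes linked to remodeler-dependent activated enhancers are induced
  (+2) during differentiation and lose that induction in the knockout
  (KO effect −2·(1−δ)·induction, i.e. full reversal at δ = 0.5); Polycomb
  genes are derepressed (+2) as their H3K27me3 decays; a configurable set
  of repressed and non-Polycomb-up genes completes the landscape.

Not emulated: sequence-level reads (FASTQ), mappability and GC bias,
fragment-length effects, strand-specific exonuclease pileups, chromatin
interactions for enhancer–gene pairing (nearest-gene is the contract),
and realistic genome scale. Passing tests therefore demonstrate that the
analysis recovers planted structure under idealized noise of the right
family — they do not demonstrate robustness to alignment artifacts,
copy-number variation, or batch effects in real data.

## Study conditions and problem sizes

The default study conditions are a 20 Mb genome (4 × 5 Mb), 600 genes,
100 static + 100 activated + 30 ESC-only enhancers (~11.5 enhancers/Mb),
50 Polycomb genes, ChIP depth 1e6 and RNA depth 2e6 per library, two
replicates. Studies that replicate across 20 seeds (peak calibration,
replicate intersection, the bound-versus-unbound sign test, determinism)
run on proportionally reduced landscapes (e.g. 1 × 5 Mb with a
quarter-size landscape) that preserve the per-Mb densities and every
condition parameter; the differential-expression study uses 2000 genes on
30 Mb with 300 planted 4-fold effects, and permutation calibration uses
200 datasets of 150 query / 60 reference intervals on 1 Mb. These sizes
are the package's replication design and are fixed in
`chromdyn.validation`.

## Known limitations

- The Poisson caller has no fragment-shift or peak-shape model; it is a
  window scanner, appropriate for the punctate marks simulated here and
  not for broad domains (H3K27me3 is consumed as density, never called).
- The global-dispersion differential test shares one dispersion across
  genes; gene-specific dispersion would require more replicates than the
  study design provides.
- Nearest-gene enhancer assignment is a coarse proxy for regulatory
  pairing; the correlation it yields should be read as a lower bound.
- 2-means on a one-dimensional density summary assumes the two gene
  groups are separated in total promoter H3K27me3; heavily overlapping
  groups would need a mixture model with an explicit decision boundary.
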