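# Methods

This note records the models, parameter choices, and numerical decisions
behind the package, and what the synthetic validation does and does not
demonstrate about real data.

## Coordinates and formats

All coordinates are 0-based half-open internally; BED/bedGraph are emitted
natively and GFF3 is converted on read/write. Midpoints of even-width
intervals break ties toward the lower coordinate. Gene models are
single-isoform (TSS at the gene's 5′ boundary; promoter = 2000 bp upstream
unless a window states otherwise).

## Footprint statistic

For each DHS, every window of width w ∈ {11, 13, …, 25} with shoulders of
35 bp is scored as two one-sided binomial tails: forward-strand cuts in the
left shoulder out of (left shoulder + window) forward cuts, success
probability s/(s+w), and symmetrically reverse-strand cuts in the right
shoulder. The score is the sum of the two log₁₀ upper-tail probabilities;
the best width per position is kept, candidates scoring below −10 are
selected greedily (ascending score, ties to the leftmost start) without
overlap. Strand-awareness makes the statistic sensitive to the
double-flanked cut pattern of genuine protection and symmetric under
strand-swap-plus-mirror. The binomial tail is computed by
`scipy.stats.binom.logsf`, verified against direct log-space summation of
the pmf to < 1e−10 in log₁₀ units for all totals ≤ 200.

Widths and the 35-bp shoulder are package defaults exposed in configuration;
the −10 score cutoff and the 4-bp extension applied before motif scanning
are fixed analysis constants.

## Hexamer bias and the FLR

A cut is assigned to the base immediately 3′ of the nick on the read's
strand; its context is the 3 bases on either side, read in strand
orientation (reverse-complemented for −). The bias table is
rate(h) = (cuts with context h + pc) / (genomic positions with context h + pc),
normalized to mean 1 over observed hexamers; unobserved hexamers are set to
1 and flagged. Pseudocount pc defaults to 1.

Each footprint's depletion statistic is x = ln((o_in/e_in)/(o_out/e_out)),
where o are observed pooled cuts inside the footprint and in its 35-bp
shoulders and e are the bias-expected weights (per-base mean of the two
strand contexts; N-contexts weigh 1). A two-component Gaussian mixture over
{x} is fitted by EM (k-means initialization with a fixed seed, variance
floor 1e−6, convergence at |Δ log L| < 1e−9; the log-likelihood is
non-decreasing by construction and asserted in tests). The footprint
component is the lower-mean component; FLR_i = log π_f f_f(x_i) − log
π_b f_b(x_i). A genuine footprint at protection φ has x ≈ ln φ, while a dip
reproduced by the deproteinated control has x ≈ 0, so the FLR ≥ 0 filter
separates protection from sequence bias. Degenerate fits (a vanishing
component or coincident means) set all FLR to −1 and are flagged rather
than trusted.

## Exact PWM p-values

Log₂-odds scores against the background are discretized to a 1e−3-bit grid
at matrix construction; the discretized matrix *is* the score function, so
the score distribution of background-random width-w sequences — built by one
shift-add convolution per column — yields p-values that are exact for the
scores the scanner reports (verified against exhaustive enumeration over all
4^w sequences to < 1e−9). Zero probabilities are floored at −20 bits per
position before discretization. Reverse-strand hits score the
reverse-complemented window with the forward matrix and share its null
distribution. The default scan threshold is p ≤ 1e−4; non-overlapping
counting is greedy by ascending p-value with leftmost-start, then
lexicographic motif-id tie-breaks, making the count independent of input
order.

## Enrichment and trajectories

Backgrounds are per-group hit proportions in hyperconserved DHSs intersected
with gene loci (gene body plus 1.5-kb promoter); enrichment is
log₂((obs+ε)/(exp+ε)) with ε = pseudocount/total (pseudocount 1 by default)
so empty groups stay finite. Log base 2 is used throughout and stated in
outputs. Binding trajectories are per-time-point per-group hit proportions
(proportioning removes depth differences), mean-centred across the five
time points; dark-vs-light correlation defaults to Pearson with Spearman
available. For background gene-locus selection, the low-expression filter
defaults to dropping the bottom quartile of mean normalized expression.

## Expression analyses

Quantile normalization maps every sample onto the mean order-statistic
vector, with ties receiving the mean of the order-statistic means they span.
Sample-mean scaling divides each sample by its mean (idempotent; a value of
1 is the sample average). Genes lacking a 3′UTR receive a 339-bp
pseudo-3′UTR beyond the stop codon, clipped at chromosome ends.

DE calls intersect two independent tests after a low-expression filter
(mean count ≥ 5): an exact conditional Poisson test on replicate-summed
counts (binomial given the total) and a Welch t-test on log₂(count+1) with
a fold-change floor (default 1.5), each BH-corrected at α = 0.05. The
intersection is deliberately conservative: the null false-robust-call rate
is bounded by α. A known limitation of the per-gene stand-in: under strong
extra-Poisson dispersion the n = 3 Welch test loses power (production
tools share dispersion information across genes, which is out of scope
here); the stated power property (≥ 90% for a 4-fold change at mean 100,
n = 3) holds under Poisson sampling noise, and the calibration property
holds under both count models.

The cross-species contrast compares per-orthogroup induction (24 h vs 0 h,
pseudocount 0.01) between sample-mean-scaled matrices and reports log₂ of
the induction ratio. Quantile normalization is *not* applied on this path:
on a small synthetic transcriptome its order-statistic averaging across
time points shrinks the few extreme induced values by ~0.25 log₂,
systematically biasing the planted contrast; sample-mean scaling alone is
sufficient for cross-species comparability of the ratio-of-ratios. Time
points are aligned by nearest label (e.g. a 3 h sample matches a 2 h query).

## Synthetic scenarios

The generator draws everything from one seed via per-component
`default_rng([seed, k])` streams, so outputs are byte-identical under a
fixed scenario.

- **Genome and genes.** Random sequence at GC 0.38 (plant-like); equal gene
  slots with ≥ 2.2 kb promoter margins; gene models of 5′UTR (100 bp),
  CDS–intron–CDS (300/150/300 bp) and an optional 200-bp 3′UTR (30% of
  genes lack one, exercising the pseudo-UTR fix).
- **Accessibility.** Each gene has a promoter DHS ([−400, +100) around the
  TSS, rectangular with 50-bp linear shoulders) open at all time points;
  30% as many intergenic DHSs open only in the light. After illumination
  (0.5–4 h) the [−500, 0) upstream window gains +50% cutting rate,
  emulating promoter-proximal opening.
- **Cuts.** Per-base Poisson with rate = depth × accessibility × hexamer
  bias × (φ inside an occupied footprint), split evenly between strands.
  The bias table is lognormal (σ = 0.6) with a trap hexamer (AAAAAA) forced
  to rate 0.1; decoys are 26-bp trap runs planted in motif-free promoters,
  producing dips that the deproteinated control (uniform accessibility,
  bias only) reproduces. The default scenario uses 10 cuts/bp in DHSs over
  1 Mb; the footprint-recovery scenario uses 2 Mb, 200 footprints at
  φ = 0.2, 30 cuts/bp, and 100 decoys, with a ≥ 1e6-cut control.
- **Motifs.** Eight 8-bp consensus LRE-family motifs (G-box ×2, I-box,
  GT-box, E-box, TGA, CCA1-like, HD) planted into half of the promoters
  (the other half stay motif-free as negatives); an exact 8-mer match has
  p = 0.25⁸ ≈ 1.5e−5, below the 1e−4 scan threshold. C4-like genes carry
  3 extra LRE instances for species A versus 1 for species B. Footprint
  occupancy is either constant or "inverted" (alternating groups bound in
  dark/24 h versus 0.5–4 h), the design behind the trajectory
  correlations.
- **Expression.** Negative-binomial (dispersion 0.05; Poisson by config)
  counts for classes induced (→3× by 24 h), repressed (→0.5×), flat, and a
  C4-like module (→4× in species A; species-B orthologs compressed to 2×).
  The species-contrast scenario uses 1000 genes with a 2.5% C4-like module
  and 5%/5% induced/repressed so that sample-mean normalization shifts the
  24 h library mean by only ~0.06 log₂ and 25 orthologs average per-gene
  sampling noise (sd ≈ 0.4 at dispersion 0.05, n = 3) to ≈ 0.08 — sizes
  chosen from this variance budget.

Problem sizes throughout (1–2 Mb genomes, tens to hundreds of genes) are
chosen so the full validation runs in seconds to minutes on one CPU while
every statistical property is measured at its stated tolerance.

## What the synthetic validation does not show

The generator emulates the statistical structure the analysis assumes —
Poisson cuts, rectangular accessibility, exact consensus planting,
independent hexamer effects. Real DNase-seq adds mappability and
duplication artifacts, read-level biases, chromatin heterogeneity across
cell types, correlated motif occurrences, and isoform complexity, none of
which are modelled. Passing recovery tests therefore demonstrates
correctness of the implementations and calibration of the statistics under
their assumed models, not end-to-end accuracy on arbitrary real libraries.
Genome-scale counts from real data (tens of thousands of DHSs, hundreds of
thousands of DGFs) are not reproduced at these desk scales.
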