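# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention). Overlap between two
intervals means at least one shared base; touching half-open intervals
([0,10) and [10,20)) do not overlap and are not merged. Peaks carry a summit
as an offset from the peak start; a narrowPeak column 10 below zero falls
back to the peak midpoint. Peaks extending past a contig end are clipped
with a logged warning rather than rejected.

## Tn5 cut-site inference

A read's cut site is its 5' end shifted +5 (plus strand) or −4 (minus
strand), where the 5' end of a minus-strand read is its rightmost aligned
base (`end − 1`). This is deliberately the literal +5/−4 convention, which
differs by one base from the "+4/−5" shift used in much of the ATAC-seq
literature; the strand symmetry it implies (a plus read at p and a minus
read with 5' end p+9 report the same site) is asserted in the tests. Each
site is extended 5 bp in both directions into an 11-bp event before
accumulation into dense per-contig integer tracks. Reads whose fragment
span exceeds 2,000 bp are discarded when mate information exists;
single-end records pass unfiltered. One event is counted per read (each
read end is an independent insertion).

Dense per-base tracks are appropriate for the synthetic genomes this
package targets (tens of Mb); a bedGraph export provides a sparse
representation for interchange.

## Footprint profiles and the protection-ratio estimator

The aggregate profile is the raw mean of track counts per position across
motif hits in an even window (default 100 bp) centered on each motif, with
no per-site normalization. The motif center for even widths is the
left-of-center base, `floor((start + end − 1)/2)`; with strand orientation
enabled, minus-strand hits use the mirror-equivalent (right-of-center) base
and a reversed window, which makes the oriented profile exactly invariant
under mirroring the genome and flipping strands. Hits whose window crosses
a contig edge are dropped and counted.

Footprint depth is summarized as the ratio of mean core counts
(|d| ≤ 9 by default) to mean flank counts (15 ≤ |d| ≤ 45), with a delta-
method standard error `r·sqrt(1/C + 1/F)` from the summed raw counts.
This SE is only calibrated on an *unextended* event profile (track built
with extension 0), where per-position counts are independent Poisson; on
the extended profile each insertion spreads over 11 neighboring positions
and the nominal Poisson SE understates the sampling error by roughly
`sqrt(11)`. The estimator therefore always consumes raw events; the
extended profile is the display quantity. The default core and flank
windows sit strictly inside the planted protected (±10 bp) and
flank-enriched (±50 bp) zones of the synthetic generator, so the ratio's
expectation is the planted protection factor. For the same reason the
flatness goodness-of-fit on structure-free data is computed on insertion
events, not extended counts, where the chi-square null actually holds.

Summit-to-motif distances are signed (`summit − motif_center`), recorded
for every (peak, overlapping motif hit) pair within a 400-bp window; a
best-hit-only mode keeps one highest-scoring hit per peak.

## Reads-in-peaks normalization

Experiments with different signal-to-background levels are equalized by
reads-in-peaks (RiP) rather than library size. Reads are counted (once
each, ≥1 bp overlap) against a merged peak atlas produced upstream. The
experiment with the smallest RiP is the reference (RiP ties break by
label, making the plan order-invariant); each other experiment's target
library size is `round(RiP_ref / FRiP_i)`, clamped to its pool, so the
expected post-subsampling RiP equals the reference's. Subsampling is
uniform without replacement and reproducible from a seed; per-experiment
streams are derived from the plan seed and the experiment label (an FNV
hash), so results do not depend on iteration order. Sampling operates on
read records as given; pooling replicates is the caller's choice.

## Transition classification

Regions are the merged union of the four input peak sets (ChIP and ATAC at
two timepoints) — a deliberate, documented choice, as the original
region-building of such analyses is typically underspecified; it is the
main reproducibility caveat of this module. Each region's per-stage state
derives from ≥1 bp overlap with the corresponding set: (chip, atac) →
P / A / PA / −. Regions with no ChIP peak at either stage are dropped.
The full ordered-pair alphabet is retained (12 possible groups after
filtering); the two biologically named groups are `pioneered` (P→PA) and
`bound_closed_both` (P→P). Group comparisons between two tracks (e.g. wild
type vs mutant accessibility at pioneered sites) report per-bin mean
profiles over the group's regions and their difference; statistical
differential testing is out of scope.

## Signal matrices and k-means

Matrices are mean-per-bin signal over `[anchor − flank, anchor + flank)`
per region (anchor = summit or midpoint), zero-padded and flagged at contig
edges; windows not divisible by the bin count split as evenly as possible.
k-means uses k-means++ initialization from an explicit seed and Lloyd
iterations implemented in-package so the within-cluster sum of squares is
recorded per iteration (the objective trace must be non-increasing, and
the tests assert it; sklearn's KMeans serves as an independent cross-check
on separable data). Empty clusters are repaired by seizing the point
farthest from its center. Because heatmap-clustering tools rarely fix
label order, clusters are relabeled by decreasing centroid mean signal so
outputs are comparable across runs; an optional per-row rank transform
approximates rank-based clustering and is labeled an approximation.

## Regulatory domains and enrichment

Basal domains are strand-aware windows around the TSS (default 5 kb
upstream, 1 kb downstream). Extension reaches outward from each basal edge
until the nearer of the 1 Mb cap or the nearest neighboring gene's basal
domain edge; a neighbor whose basal domain already overlaps the gene's own
clamps extension on that side to zero, and extension never truncates the
gene's own basal domain. Domains are clipped at contig ends when contig
sizes are supplied. The implementation uses sorted prefix/suffix edge
arrays; the tests compare it gene-by-gene against a naive linear-scan
oracle on random layouts. Peaks are assigned to every gene whose extended
domain contains the peak midpoint (midpoint containment, not any-overlap);
multi-assignment is expected where basal domains overlap.

Term enrichment uses the minimum-likelihood two-sided hypergeometric test:
p is the sum of P(X = x) over all outcomes no more probable than the
observed k (with a 1e-7 relative tolerance for floating-point ties), which
reduces to the classical two-sided Fisher convention. A doubled-tail
variant is available. Bonferroni correction divides by the number of terms
actually tested — terms with no universe genes after intersection are
excluded from both testing and the denominator. The universe is an
explicit required input. Because the test is exact and discrete it is
conservative: under a true null the fraction of p < 0.05 sits slightly
below 5% (typically 2–5% in the calibration runs), which is expected
behavior, not an error.

Two stated invariants were corrected to their true forms during
development: the observed side's tail (not the upper tail unconditionally)
is bounded by the two-sided p, and extension *flanks* (not whole extended
domains) never intersect a neighbor's basal domain — adjacent genes'
extended domains legitimately share the intergenic gap.

## Synthetic data: what it emulates, and what it does not

The generators plant ground truth at desk scale on a single synthetic
contig (default 10 Mb):

- **Landscape**: 5,000 non-overlapping regions (400 bp wide, ≥600 bp gaps)
  with planted transition labels — 500 pioneered, 300 bound-closed-both and
  4,200 spread over the remaining 13 state pairs. Peaks are emitted exactly
  at region spans, so classification recovery is deterministic; this
  validates the classifier's logic, not its robustness to peak-boundary
  noise.
- **Cut sites**: Poisson insertions per base; intensity ×3 within ±50 bp of
  each motif center and ×0.2 (protection) within ±10 bp, defaults chosen as
  a realistic mid-depth footprint; 50,000 expected events over 200 motifs.
  Reads are emitted on random strands positioned so the +5/−4 rule recovers
  the insertion base exactly. Fragment lengths follow a sub-nucleosomal +
  mono-nucleosomal mixture with a 1% >2 kb tail that exercises the fragment
  filter.
- **RiP experiments**: reads land fully inside a fixed disjoint peak comb
  with probability FRiP, else fully outside with a safety margin, so
  realized RiP is exactly binomial.
- **Annotation**: 1,000 genes, one term each from 10 terms; the emitted
  gene set of 50 is drawn without replacement with weight = effect size for
  planted-term genes (effect 1 is the null; default 4 is a clearly
  detectable but non-degenerate enrichment).

Not emulated: sequence content, GC/mappability bias, duplicate reads,
replicate structure, peak-caller noise, multi-contig genomes beyond
interface testing. Passing tests therefore demonstrate correctness of the
computations under their stated models, not performance on real libraries.

All randomness flows through one `numpy.random.Generator` seeded from the
config; fixed seed gives byte-identical outputs.

## Problem sizes and numerical choices

Simulated problem sizes (50,000 events, 5,000 regions, 200 motifs,
1,000 genes, 200 enrichment replicates) were chosen so planted effects are
recovered with comfortable statistical margins while the whole suite and
the acceptance script each run in well under a minute of compute per
stage. Subsampling targets round to nearest and clamp to the pool.
Enrichment ties sort by term label; k-means ties are resolved by the
seeded initialization. Degenerate inputs (empty peak sets, zero-width
flanks, single-term annotations, k = 1) are exercised in the tests.
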