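# pioneerscan

Pioneer transcription factors bind nucleosomal, non-accessible chromatin and
promote its subsequent opening, letting other factors in. Detecting that
behavior from sequencing data takes a particular chain of computations:
inferring Tn5 transposase cut sites from ChIPmentation/ATAC-seq reads,
aggregating them into footprints around binding motifs, normalizing
experiments with different signal-to-background levels so their peak states
are comparable, classifying genomic regions by their joint binding/
accessibility state across two developmental timepoints, and asking which
gene expression programs the resulting site groups point at.

`pioneerscan` implements that chain as a tested, reusable Python library and
CLI, together with a synthetic-data module that plants known ground truth
(footprint depth, transition-group labels, per-experiment FRiP, enriched
annotation terms) so every stage can be validated end to end without any
external download.

## The computations

- **Tn5 cut sites** (`cutsites`). The insertion point is the read's 5' end
  shifted +5 on the plus strand and −4 on the minus strand (the 5' end of a
  minus-strand read being its rightmost aligned base); each site is extended
  5 bp both ways into an 11-bp event. Read pairs whose fragments exceed
  2 kb are discarded. Note this implements the literal +5/−4 rule, one base
  off from the "+4/−5" variant common elsewhere in the ATAC literature.
- **Footprints and summit–motif geometry** (`footprint`). Mean cut-site
  counts per position in a 100-bp window centered on motif hits (optionally
  strand-oriented), a protection-ratio estimator (core/flank intensity with
  a Poisson delta-method SE, computed on unextended events), and the signed
  distribution of peak-summit-to-motif-center distances within a 400-bp
  window.
- **Reads-in-peaks normalization** (`ripnorm`). Reads are counted inside a
  merged peak atlas; the experiment with the fewest reads-in-peaks (RiP)
  becomes the reference, and every other experiment is subsampled to
  `round(RiP_ref / FRiP_i)` total reads, equalizing expected RiP across
  experiments.
- **State transitions** (`transitions`). A union atlas of merged
  ChIP + ATAC peaks at two timepoints; each region's per-stage state is
  P (ChIP only), A (ATAC only), PA (both) or −. Regions never ChIP-bound are
  dropped; `P->PA` is the *pioneered* class (bound while closed, open
  later), `P->P` the bound-but-never-accessible class.
- **Signal clustering** (`clustering`). computeMatrix-style binned signal
  matrices over regions and seeded k-means (k-means++ init, Lloyd
  iterations with an exposed objective trace, clusters relabeled by
  decreasing mean signal).
- **Gene assignment and enrichment** (`regdomains`). GREAT-style
  basal-plus-extension regulatory domains (5 kb up / 1 kb down / 1 Mb cap,
  extension stopping at the nearest neighboring basal domain), midpoint
  peak-to-gene assignment, and a two-tailed (minimum-likelihood)
  hypergeometric enrichment test with Bonferroni correction.

## Worked example

Run the full pipeline on self-generated synthetic data:

```python
from pioneerscan.pipeline import RunConfig, run

report = run(RunConfig(seed=42, outdir="demo_run"))
print(report["stages"]["transitions"]["n_pioneered"])
print(report["stages"]["footprint"]["protection_ratio"])
print(report["stages"]["rip_normalization"]["post_rip"])
```

With seed 42 this prints, among the rest of the report (also written to
`demo_run/report.json`):

- `n_pioneered: 500` — the classifier recovers exactly the 500 planted
  pioneered regions out of 5,000 (4,031 survive the ChIP-required filter;
  the 969 factor-free regions are dropped, as planted).
- `protection_ratio: 0.152` (SE 0.049) — the footprint depth estimate for a
  planted protection factor of 0.2, within one standard error.
- `post_rip: {exp_a: 5002, exp_b: 5038, exp_c: 4968, exp_d: 5067}` — four
  experiments generated with FRiP 0.1/0.2/0.3/0.4 and 50,000 reads each end
  up with matching reads-in-peaks after planning and subsampling
  (reference RiP 5,002).
- the enrichment stage ranks the planted term first
  (`p = 7.4e-07`, Bonferroni-corrected `7.4e-06`).

The same stages are exposed as shell commands:

```sh
pioneerscan simulate --out simdir --seed 42
pioneerscan transitions \
    --chip-t1 simdir/chip_t1.narrowPeak --atac-t1 simdir/atac_t1.narrowPeak \
    --chip-t2 simdir/chip_t2.narrowPeak --atac-t2 simdir/atac_t2.narrowPeak \
    --out groups.bed
pioneerscan footprint --reads simdir/fragments.bed --genome simdir/chrom.sizes \
    --motifs simdir/motifs.bed --out profile.tsv
```

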