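# Methods

This note documents the models, parameter choices and numerical
conventions behind `cardioquant`, and what the synthetic benchmarks do
and do not demonstrate.

## Pol II gene-body enrichment

### Coverage model and normalization

Coverage tracks are fixed-width binned values per chromosome
(`BinnedTrack`), read from WIG (1-based on disk, converted to the
internal 0-based half-open convention) or bedGraph (passed through).
Zero bins may be omitted on disk; readers treat missing bins as zero, so
sparse MACS-style output round-trips losslessly. Chromosome names are
matched exactly — no `chr` aliasing — and a preflight check reports
name-set mismatches between track and gene table rather than silently
quantifying nothing.

Raw per-bin read counts are normalized to read density per million
mapped reads per bp: `d = v / bin_width / (depth / 1e6)`. Library depth
is not recoverable from a WIG file, so it must be supplied; requesting
normalization without it is an error, and normalizing twice is an
error. Tracks that are already densities can be declared as such
(`normalized` flag / `--prenormalized`), since upstream tools differ in
whether they emit counts or scaled densities.

### Block partition

The gene body (TSS→TES, length `L ≥ 10` bp) is cut into `n_body = 10`
blocks at boundaries `d_i = round(i·L/10)` **measured from the TSS along
the transcription direction**. Cumulative rounding makes the blocks tile
the body exactly with integer widths differing by ≤ 1 bp, and anchoring
at the TSS makes the partition mirror-symmetric: a strand-reflected gene
over mirrored coverage yields the exactly reversed 25-block profile
(covered by a test using dyadic bin values so every float sum is exact).

Flank blocks — 5 upstream of the TSS, 10 downstream of the TES — default
to one body-block width `⌊L/10⌋` each, so the whole axis is in units of
gene-length tenths, matching proportional metagene plots; a fixed bp
width can be supplied instead. Flanks reaching below position 0 (or past
a declared chromosome length) are clipped and flagged and their value is
averaged over the clipped extent; a clipped *body* raises, because the
body score is the headline quantity.

Block values average the per-bp density over the block; bins straddling
a block boundary contribute pro rata by overlap length, which makes the
result independent of bin phase and exactly equal to a per-bp
brute-force expansion (tested at 1e-9 relative on random tracks). Genes
are quantified independently; overlapping genes share density.

### Score, ranking, filtering

The enrichment score is the sum of the 10 body-block average densities —
units density/bp, already length-normalized by construction. A constant
density `d` gives score `10·d` for any gene length. Two conditions are
compared by `fold = (score_B + ε)/(score_A + ε)`; genes with both
scores zero get fold exactly 1. The default pseudocount ε is the 5th
percentile of the positive control scores. That choice stabilizes
near-zero denominators on realistic data, where scores span orders of
magnitude and the 5th percentile sits near the noise floor; on inputs
whose scores are homogeneous (including this package's flat-background
simulations, where every control score is strictly positive and of the
same magnitude) it compresses all ratios toward 1, so recovery
benchmarks use ε = 0, i.e. the exact ratio. ε is a public parameter and
is recorded in the run log.

Filtering keeps genes with fold strictly above the threshold (default
1.5; a stricter twofold cut is one flag away), optionally restricted to
genes with an assigned peak. Peak-to-gene assignment is ≥ 1 bp overlap
with the gene body extended 1000 bp 5′ of the TSS; windows are
half-open, so a peak ending exactly at the window start is not assigned,
and one peak may be assigned to several genes. Ranking is by fold ratio
or by treatment score, descending, with ties broken lexicographically by
gene name so output order is deterministic.

## Track simulator

`simulate_tracks` lays non-overlapping genes (default 200, lengths
1–5 kb, alternating strands, 50 per synthetic chromosome, 12 kb spacing
so the widest flanks fit) and builds an expected per-bp rate:

* background 0.1 reads/bp everywhere;
* a promoter-proximal peak — 5× background over one body-block width
  centered on the TSS, both conditions — reproducing the TSS-proximal
  accumulation seen in Pol II metagenes without claiming its exact shape;
* in the treatment condition, the gene body of a designated 20% subset
  is enriched by multiplying the **entire local control rate** by the
  body fold (default 2). Multiplying the whole rate, rather than adding
  a term to background only, models proportional Pol II recruitment and
  makes the expected score ratio equal the designed fold independent of
  promoter geometry.

Per-bin counts are Poisson at `rate × bin_width`, scaled so each
condition's expected total equals the configured depth (1e6 reads);
Poisson is sufficient for recovery testing, and overdispersion can be
emulated by lowering depth. Identical seeds give byte-identical WIG
output. Ground truth records each gene's designed fold, and the result
carries each condition's pre-scaling factor so tests can verify the
exact ×2 construction.

**Known bias the benchmark surfaces.** Because both libraries are scaled
to the same total, the extra reads that enrichment adds to the treatment
library deflate all its densities slightly: the recovered fold is
`F × (total_control_rate / total_treatment_rate)` ≈ 1.90–1.93 for
F = 2 at defaults rather than 2.00. This is a property of per-million
depth normalization itself — real two-condition comparisons normalized
this way carry the same compression — not of the block quantification,
which is exact against its oracle. The recovery benchmark (median fold
within 10% of the designed value; enriched/non-enriched ranking
AUC ≥ 0.95 at 1M reads) passes with this bias included.

## Single-cell imaging quantification

### Segmentation

Nuclei: Gaussian smoothing (σ = 2 px), global Otsu threshold, hole
filling, removal of objects under `min_area` = 50 px, then a Euclidean
distance-transform watershed whose seeds are distance maxima at least
`split_min_distance` = 10 px apart, splitting touching nuclei. Cell
territories: a watershed on the inverted smoothed marker intensity,
seeded by the nucleus labels and restricted to the thresholded marker
area plus the nuclei; marker components the watershed cannot reach
(no seed inside) are divided among the nearest nuclei by Euclidean
distance; an optional `max_cell_radius` clips each territory around its
nucleus centroid. Territories are disjoint, each contains its nucleus,
and a nucleus with no surrounding marker keeps a nucleus-only territory
with an empty cytosol.

Automatic thresholds are rejected when Otsu's effectiveness metric
(between-class over total variance) falls below 0.75: for pure Gaussian
noise the optimal split achieves exactly 2/π ≈ 0.64, while genuine
foreground at working contrast exceeds 0.95, so a signal-free channel
yields an empty mask instead of hallucinated objects. All operators are
deterministic: identical inputs give bit-identical label rasters and
tables.

### Classification and measurement

A cell is marker-positive (a cardiomyocyte, when the marker is troponin
I) iff the marker mask covers at least θ = 0.5 of its cytosolic area.
The gate uses the cytosol, not the nucleus centroid, because sarcomeric
troponin I is cytoplasmic; a cell with an empty cytosol is negative.
The cytosol is the set difference territory-minus-nucleus — separating
compartments by masks, not by subtracting intensities — so nucleus and
cytosol are disjoint, their union is the territory, and the territory EU
integral equals the nuclear plus cytosolic integrals by construction.

EU statistics are mean and integrated intensity over each compartment
after subtracting a per-field background (median EU outside all
territories; configurable to none), with negative post-subtraction
pixels clamped to zero. Cell area is the territory pixel count
(converted with `pixel_size²` when given). Cells touching the field
border are measured but flagged and excluded from condition summaries by
default, since truncated territories bias area statistics. Each nucleus
keeps its own territory — binucleated cardiomyocytes are reported
per-nucleus, matching a per-nucleus reading of "nuclear RNA per cell";
merging is deliberately not applied.

Condition summaries average nuclear EU, cytosolic EU and area over
cardiomyocytes only and optionally divide by a reference condition
(reference = 1). Group means are reported without p-value machinery;
significance testing is left to downstream tools.

## Image simulator

`simulate_image_fields` draws disk cells (radius 26–34 px) with a
concentric nucleus disk (8–10 px) on 384×384 fields, 5–8 cells per
field, placed by rejection sampling at a minimum centroid spacing of
`2·r_max + 4` px and kept clear of the border, so ground-truth areas are
exact pixel counts and no two cells touch. Exactly
`round(fraction · n)` cells per field are marker-positive (default
60%). Channel levels are absolute: nuclei 400 over background 20;
marker 300 over 20 on positive cells; EU 500 in nuclei and 150 in
cytosol over background 50. Additive Gaussian noise (σ = 10) gives an
SNR of ≈ 10 for the dimmest compartment; negative pixels are clamped at
zero (negligible truncation at these levels). The measurable truth for
a compartment is therefore its **contrast**, level minus background
(450 nuclear, 100 cytosolic), which is what recovery is judged against.

What the simulator does *not* model: irregular cell shapes, optical
point-spread blur, uneven illumination, multinucleation, overlapping
cells, and intensity variation between cells of one condition. Passing
recovery tests therefore demonstrates that the measurement chain is
unbiased and deterministic on geometrically ideal input — segmentation
robustness on real cytometer fields is a separate question the
parameters (smoothing, `min_area`, θ, `split_min_distance`) exist to
tune.

Residual measurement biases the benchmarks quantify: the segmented
nucleus boundary lands within ~1 px of the true edge, so a thin ring of
bright nuclear signal can leak into the cytosol mask and a ring of
cytosol into the nucleus mean — at default geometry this leaves nuclear
recovery ≈ 3.5% low and cytosolic ≈ 1% low, both inside the 10%
acceptance band; between-condition *ratios* cancel most of this shared
bias (doubled cytosolic contrast recovers as ≈ 2.01, and a 1.5× linear
size change recovers a mean-area ratio within a few percent of 2.25).

## Problem sizes and determinism

The shipped benchmarks use 200 genes at 1e6 reads per condition for the
track recovery, 100 fields for nucleus-count accuracy and compartment
recovery, 8 fields per condition for the intensity-fold experiment and
16 per condition for the size experiment (mean cell area has the
largest between-cell variance, so that comparison gets the larger
sample). All simulation and analysis code is seeded and deterministic;
pipeline reruns with identical configuration produce byte-identical
tables (floats are serialized at 10 significant digits via a fixed
format). The acceptance script derives every seed from its `--seed`
argument.
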