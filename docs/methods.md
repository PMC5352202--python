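# Methods

## Overview

`somcell` reconstructs a self-organizing-map (SOM) "expression portrayal"
workflow for single-cell RNA-seq of tumor short-term cultures, together
with a ground-truth synthetic-culture generator that makes every stage
testable end to end. The pipeline runs:

1. housekeeping-gene cell QC,
2. log-transform, quantile normalization, gene centering,
3. batch-SOM compression of gene profiles into grid "metagenes",
4. segmentation of over-expression spot modules on the summary portrait,
5. cell-group discovery from pairwise portrait correlations,
6. gene-set scoring (Fisher enrichment, per-cell GSZ) and
7. expression-inferred copy-number profiles along the genome.

## Preprocessing

Cells are kept iff at least one housekeeping gene (ACTB, GAPDH by
default) has expression strictly greater than 0 — chamber failures in
microfluidic capture express neither. Expression is then log10(x+1)
transformed (FPKM spans ~4 decades; training prototype vectors on raw
values lets a handful of giant values dominate), quantile normalized
across cells (rank-mean scheme; ties receive the mean of the rank-means
over their tied positions, making the result independent of sort
stability) and gene-centered. Whether to log-transform before quantile
normalization is genuinely open; the flag `log_transform` controls it
and defaults to on. Zero-variance genes are dropped before SOM training
(`min_sd`, default 0) since they carry no information and produce
degenerate prototype updates.

## The SOM and portraits

Genes are the mapped items: each gene is a point in R^(n_cells) and a
`grid_rows x grid_cols` grid of prototype vectors ("metagenes",
default 50 x 50 = 2,500) is fitted with the *batch* SOM algorithm.
Prototypes are initialized on the plane of the first two principal
components of the gene cloud (deterministic; the seed only adds a 1e-9
jitter to break exact ties), and each of `epochs` (default 30) passes
reassigns genes to their Euclidean best-matching unit and replaces every
prototype with the Gaussian-neighborhood-weighted mean of its genes. The
neighborhood radius decays linearly from max(grid dims)/2 to 1. Batch
training removes any dependence on presentation order, so a fixed seed
gives bit-identical maps; 30 epochs converge well within a minute at
2,000 genes x 92 cells. A *portrait* is one cell's column of the
codebook displayed on the grid; co-regulated genes occupy contiguous
territories, so a portrait shows which expression programs a cell runs.

Because the initialization is already maximally smooth (a linear ramp in
PC space), the map-organization diagnostic (mean grid distance between
each gene's unit and its most-correlated partner's unit) is *not*
monotone over epochs; the meaningful property, asserted in the tests, is
that the trained assignment is far smoother than a shuffled one.

## Spot modules

The summary over-expression portrait takes, per unit, the q = 0.98
quantile of its metagene values across cells, which makes modules
carried by rare subpopulations visible alongside the dominant ones.
`detect_spots` thresholds this map at a foreground quantile and keeps
8-connected components of at least `min_units` units (defaults 0.90 / 5;
4-connectivity splits diagonal ridges artificially). Spots are labeled
A, B, ... by decreasing peak. Member genes are those whose best-matching
unit lies in the spot, ranked by Pearson correlation with the spot's
mean per-cell profile.

The pipeline layer adds two refinements, both config-exposed and both
calibrated so that the planted modules of the preset fixtures emerge as
3–6 spots:

- **Profile-coherence splitting** (`refine_quantile = 0.0`,
  `core_merge_r = 0.5`): a component's units are clustered by
  average-linkage correlation of their prototype profiles and the
  component is split when it holds two or more groups below r = 0.5 —
  the signature of a small rare-population module caught in the halo of
  an unrelated neighbor. Average linkage is essential: single linkage
  chains unrelated modules through the blended profiles of their
  boundary units. Groups below `core_min_units = 3` units are ignored,
  and parts are re-split into connected components so spots stay
  contiguous. Two local maxima of one program correlate near 1 and never
  split.
- **One-ring dilation** (`spot_dilate = 1`): module-edge genes land on
  units just below the foreground cut through best-matching-unit
  quantization jitter; growing each final spot by one ring (units
  contested between spots stay unassigned, so spots remain disjoint)
  recovers them.
- The pipeline foreground quantile is 0.85 (the op default 0.90 suits a
  standalone map; with the refinements active the lower cut trades a few
  extra halo units for full module recall).

A spot is "on" in a cell when the mean of the cell's portrait over the
spot's units exceeds the cell's own 0.90 portrait quantile.

## Cell groups

Cells are compared by the Pearson correlation of their flattened
portraits, clustered by average-linkage hierarchical clustering on
d = 1 - r, with the number of groups chosen to maximize the mean
silhouette width over k = 2..8 when not fixed. Groups are numbered by
decreasing size. The similarity network (edges at r >= 0.3) is
presentational only.

## Gene-set scoring

Spot gene lists are tested against gene sets by a right-tailed Fisher
exact (hypergeometric) test over the universe of genes that survived
preprocessing; the default report threshold is raw p < 1e-7, with an
optional Benjamini–Hochberg mode. Per-cell set activity uses a gene set
Z-score: the set's summed normalized expression divided by
sqrt(n * var~), where var~ shrinks the cell's across-gene variance
toward the global variance with weight `lambda_shrink = 10`. The
shrinkage keeps small sets from producing unstable scores; the exact
weighting of published GSZ variants differs in detail, so this variant
is documented here rather than claimed identical to any of them.

Rare-subpopulation cells are flagged when their GSZ exceeds
median + 4 x 1.4826 x MAD of the score distribution — a robust outlier
rule whose location and scale come from the non-carrier bulk, so it
flags a well-separated carrier population of any size. A largest-gap
rule was rejected: with graded per-cell program activity the largest
gap frequently falls *inside* the carrier range.

## Copy-number inference

log2(FPKM+1) values are gene-centered across cells, clipped to ±3,
ordered by (chromosome, start) and averaged over windows of 50
consecutive genes per chromosome (sliding by default; block mode for
compact heatmaps), then each cell is re-centered at its median window.
There is no reference-cell baseline — the cultures contain no normal
cells to provide one — so the method only resolves events that differ
*between* cells: a gain carried by 100% of cells is removed by the
per-gene centering. This is the standard limitation of reference-free
expression CNV and the reason the synthetic mutant preset plants its
gains in a 60% subclone.

## The synthetic-culture generator

The generator emulates FPKM-scale microfluidic single-cell RNA-seq of
melanoma short-term cultures: 96 chambers, ~2,000 genes (scalable to
15,000), three major expression programs that partition the cells, one
program shared across two groups, two rare subpopulations, chamber
failures, library-size variation, expression-dependent dropout, and
optional subclonal chromosome-scale copy-number gains.

Model: gene g in cell c has log-latent
`L_gc = mu_g + effect * a_pc * carrier(g,c) + shift * ln2 + N(0, noise_sigma)`;
the emitted value is `exp(L_gc) * lib_c`, zeroed with probability
`min(1, dropout_rate * exp(-L_gc))`. Parameters and rationale:

| parameter | default | why |
|---|---|---|
| `n_genes` x `n_cells` | 2,000 x 96 | desk-scale: full-pipeline runs in seconds; `full_scale` gives 15,000 genes |
| `effect` | 2.0 (natural log) | strong enough for reliable program recovery, weak enough that silhouette-based k selection is not trivial |
| `activity_sigma` | 0.35 | per-(cell, program) log-normal activity: program expression is graded across carriers, as real portraits are, not binary |
| `noise_sigma` | 0.4 | per-entry biological + technical log noise |
| `library_size_sigma` | 0.3 | log-normal per-cell depth factors |
| `dropout_rate` | 0.55 | with the expression-dependent rule this leaves roughly half the entries zero, in the range of sparse FPKM single-cell data |
| `base_log_mean/sd` | 0.0 / 1.2 | log-normal FPKM baseline spanning ~3 decades |
| `gene_seed` | 7777 | baselines are drawn from their own seed: a gene's characteristic expression level is a property of the genome, identical across cultures and replicate draws — without this, joint multi-culture analysis sees a synthetic batch effect at every shared gene |
| `n_qc_fail` | 4 | chambers with ACTB = GAPDH = 0 |

Planted marker genes have their baseline floored at the population mean:
curated signature genes are detectably expressed by construction, and
unfloored draws let dropout shred the weakest markers of a 24-gene
module. Housekeeping genes are highly expressed and exempt from dropout
so the QC outcome is exactly the planted one.

Presets: `wtwt` (proliferation 45%, pigmentation 28%, stroma 27%; an
oxidative-phosphorylation module shared by the first two groups; rare
ABC/ALDH module at 10% with 16 + 8 marker genes and a KDM5B-like module
at 7%), `wtwt_replicate` (proliferation 46%, new seed), `mutwt`
(proliferation 30%; gains on chr11, chr8, chr5, chr19 carried by one 60%
subclone), `wtmut` (proliferation 36% with a dominant stromal/AXL-like
program at 45%). The split of the non-proliferative remainder of `wtwt`
into pigmentation vs stroma is a documented configuration choice, not an
observed quantity.

## What the generator does not emulate

Read-level sampling, transcript-length effects in FPKM, doublets,
cell-cycle pseudo-continuity within programs, batch effects between
replicates, and correlated gene-gene noise beyond program membership.
Passing recovery tests on these fixtures therefore demonstrates the
pipeline's correctness and its behavior under planted heterogeneity —
not performance on any real dataset.

## Known limitations

- The shared oxidative-phosphorylation module (carried by ~73% of wtwt
  cells) has the smallest gene-centered amplitude of all planted
  programs and lies on the map ridge between its two host groups;
  amplitude-threshold segmentation recovers it only sporadically. The
  four dominant spots are the three group-specific programs plus the
  ABC/ALDH module.
- Reference-free CNV cannot see fully clonal events (above).
- Joint analysis intersects gene ids across cultures, so
  culture-specific program genes absent from other cultures drop out of
  the joint map; culture identity is then carried by shared-gene
  composition shifts, which is weaker than within-culture structure.

## Problem sizes used in validation

Recovery statistics are computed on the 2,000-gene x 96-cell presets
with the 50 x 50 grid and 30 epochs (≈10 s per full run), averaging the
stochastic quantities over 10 replicate generator draws; numerical
primitives (quantile normalization, Fisher p, silhouettes, CNV
windowing) are checked exactly against brute-force oracles on small
instances.
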