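# Methods

This note documents the models, parameter choices, and numerical
conventions behind the three pipelines, and what the synthetic-data tests
do and do not establish about real data.

## Whole-mount spatial quantification

**Model.** A flattened dural whole mount is a 2D multi-channel raster with
isotropic pixel size (um/px). The vessel/landmark channel (aSMA) traces
the dural venous sinuses; signal channels (B220, Cxcl12 reporter) are
binarized and quantified relative to the sinuses.

**Registration.** Samples are aligned to a common sinus reference through
user-supplied control-point pairs. The transform family is a 2D affine
fitted by least squares (`numpy.linalg.lstsq` on homogeneous coordinates),
requiring at least three non-collinear pairs; the residual RMS in pixels is
reported per sample. Affine is the minimal stable family for mildly warped
flattened tissue; a projective fit was deliberately not made the default.
Intensity channels are resampled bilinearly, boolean masks nearest-neighbor
(preserving binarity); out-of-field pixels are zero-filled and tracked in a
validity mask so they can be dropped from per-pixel averages.

**Binarization.** Thresholds are absolute intensities fixed once per
channel per acquisition batch (`BinarizationConfig`), applied as a strict
`intensity > threshold`. There is no silent per-image auto-threshold; an
Otsu helper (`propose_batch_threshold`) only proposes a batch value.

**SPA/SDA partition.** The sinus mask is expanded by a true Euclidean
distance transform: the sinus-proximal area (SPA) is every pixel within
`dilation_um` (default 300 um) of the nearest sinus pixel, sinus included;
the sinus-distal area (SDA) is the remainder of the canvas. The radius is
real-valued (`distance_px * pixel_size <= dilation_um`), not a rounded
structuring element — the morphological-disk alternative differs on
diagonal pixels and is not used. Manually-authored exclusion masks (pineal
gland, bubbles) are subtracted from both regions and from the signal before
any counting, so excluded pixels enter no numerator or denominator.

**Coverage statistics.** For each region R: coverage% = 100 |signal ∩ R| /
|R| (percent of the region occupied) and signal-fraction% = 100
|signal ∩ R| / |signal ∩ (SPA ∪ SDA)| (percent of total signal in the
region). Degenerate cases: an empty region yields a missing coverage with a
warning; zero total signal yields missing fractions and zero coverages.
Heatmaps are arithmetic per-pixel means of the binarized masks of one
experimental group, averaging only samples valid at each pixel (exclusion
masking precedes aggregation). The BaseScope-style variant reports percent
coverage inside an axis-aligned rectangle.

**Conventions.** 0-based (row, col) indexing, pixel centers at integer
coordinates, isotropic pixel size.

## CARLIN clone-sharing statistics

**Model.** Each edited CARLIN allele sequence identifies one founder clone;
UMI counts of a transcribed barcode proxy cell numbers. An allele table is
the alleles x organs UMI matrix for one mouse.

**Filtering.** Applied exactly once, before any statistic: allele 0 (the
unedited locus) is removed, as are alleles whose total UMI count across all
organs is below two. Statistics refuse unfiltered tables unless explicitly
overridden.

**Sharing statistics** (all UMI-weighted; an allele-counting variant exists
behind `umi_weighted=False` for sensitivity analysis):

- multi-organ(a) = 100 x (UMIs in a on alleles present in >= 1 other
  organ) / (UMIs in a);
- pairwise(a, b) = 100 x (UMIs in a on alleles present in b) / (UMIs in
  a) — asymmetric by design, the denominator is organ a;
- exclusive(a, b) additionally requires the allele absent from every other
  organ in the table.

Presence means count > 0; allele identity is exact sequence equality (no
edit-distance collapsing — barcode calling is upstream of this package).
Ordering exclusive <= pairwise <= multi-organ holds by construction and is
asserted property-wise. Zero organ totals yield a missing value with a
warning. Ties are always broken count-descending then allele-id-ascending
for cross-platform determinism.

**Expansion displays.** `top_expanded` ranks one organ's alleles by UMI
count (default k = 5) with per-other-organ presence flags;
`heatmap_matrix` takes the union over organs of each organ's top-300
alleles by that organ's count (a per-tissue union; a single global top-300
is available behind `per_tissue=False`) and reports log2(count + 1), rows
ordered by max count across organs.

## Single-cell QC and marker specificity

**Quality network.** Eight per-cell metrics: percent of UMIs in OXPHOS,
mitochondrial, ribosomal-protein, and immediate-early gene sets; percent of
UMIs in the cell's 50 highest-count genes; percent in lncRNAs; log2
distinct genes; log2 total UMIs. Gene-set membership lists are supplied by
the user (the synthetic generator ships its own); no ontology is bundled.
Metrics are z-scored per metric (zero-variance metrics contribute zero), a
shared-nearest-neighbor graph is built over the k = 20 nearest neighbors in
the 8-dimensional metric space with Jaccard edge weights (zero-overlap
edges pruned), and communities are found by Leiden modularity optimization
at resolution 1.0 with a fixed seed. A community is flagged when the
absolute median z of its members exceeds 2 on any metric; flagged cells are
reported with the triggering metrics. k, resolution, and the outlier
threshold are configurable; the defaults are this package's choices, since
only the algorithm family is standard.

**Hard filters.** Keep a cell iff detected genes > 500 AND 0% <
mitochondrial UMI percent < 10% — all bounds strict, so a cell at exactly
500 genes, exactly 0% mito (no mitochondrial reads at all, typically a
stripped nucleus or artifact), or exactly 10% mito is removed. The
zero-mito arm can be disabled (`require_nonzero_mito=False`).

**Differential expression.** Counts are normalized per cell to the median
library size and log1p-transformed; each gene gets a two-sided
Wilcoxon/Mann-Whitney rank-sum test (SciPy, exact for small tie-free
groups, tie-corrected asymptotic otherwise), Benjamini-Hochberg adjustment
across all genes in the comparison, and log2 fold change computed as
log2(mean_target + 1) - log2(mean_comparator + 1) on the linear normalized
scale — the +1 pseudocount keeps all-vs-none genes finite and makes the
0.585 threshold a 1.5-fold change in shifted means. Genes constant across
both groups get p = 1 by convention.

**Specificity ranking.** A candidate passes when log2FC >= 0.585, adjusted
p <= 0.05, and >= 70% of target cells express it (conjunctive; order of
application is immaterial). Specificity = pct_target / pct_comparator.
When no comparator cell expresses the gene the ratio is undefined; the
comparator percent is floored at the percent equivalent of a single
comparator cell (100 / n_comparator), keeping scores finite while still
rewarding absence — floored genes are marked. Ranking is specificity
descending, ties by pct_target descending then gene name.

## Synthetic data generators

All generators are pure functions of their config (seed included); one
master `SeedSequence` per call is split into independent child streams per
sub-process (placement vs counts vs noise), so adding noise never perturbs
placement.

**Whole mounts.** The sinus is parameterized as centerline polylines (a
sagittal trunk meeting two transverse branches at a confluence) with a
width in um, rasterized via a distance transform — so the exact sinus mask
and the exact 300-um band are known. Signal pixels (default 30 clusters x
40 px on a 256x256 canvas at 10 um/px) are placed collision-free: each
cluster is assigned to the proximal band with probability
`proximal_fraction` and its pixels sampled without replacement from the
assigned region near a cluster center, so the mask cardinality is exact and
the realized proximal fraction is Binomial(n_clusters, p)-distributed
(pixel-level Binomial(N, p) in `"uniform"` mode). Channels are the masks at
intensity 1 plus uniform background noise below 0.5, so thresholding at 0.5
recovers the ground-truth masks exactly. An optional bright blob with its
own truth mask mimics pineal autofluorescence and is never overlapped by
signal. Not emulated: PSF blur, autofluorescence spectra, stitching seams,
real sinus-tracing error — so passing recovery tests demonstrates the
statistics, not robustness to segmentation error on real images.

**Allele tables.** Defaults: 2000 founders, four organs (dura, calvarial
BM, leg BM, spleen), geometric per-organ clone sizes with mean 5 (shifted
to minimum 1 UMI — heavy-tailed, matching the concentration of UMIs in a
few expanded clones while keeping closed-form moments; the real CARLIN
clone-size law is unknown, so the family is configurable), unedited
allele-0 fraction 0.3 of UMIs. Multi-organ founders seed a uniformly-sized
(2..n_organs) weighted subset of organs. The ground-truth sharing is
enumerated from the founder map over alleles passing the total-UMI filter,
so "computed equals truth exactly" is well-defined. Not emulated:
sequencing error in barcodes, allele collision, V(D)J structure.

**Expression matrices.** Poisson-lognormal background counts (per-gene
lognormal means, per-cell lognormal library factors), planted markers that
override their column with Bernoulli(pct) x (1 + Poisson) counts, named
gene-set blocks (mt-/Rps/Ndufa/Fos/Gm prefixes) with the baseline
mitochondrial fraction recentered to 5% per cell, and an optional planted
low-quality subpopulation with mito fraction recentered at 0.5 and gene
detection thinned to 30% — a > 3-sigma shift on the mito metric relative
to normal cells. Realized percent-expressing values are recomputed from
the final matrix into the truth object. Not emulated: doublets, ambient
RNA, batch effects.

## Problem sizes and numerical tolerances

The test and acceptance suites run on deliberately small instances: oracle
equivalence on canvases <= 64x64 (exhaustive all-pairs distance scans stay
exact and fast), 500-2000 founders per allele table, 400-600 cells x
120-220 genes per expression matrix, 10-100 seeds per Monte-Carlo check.
These sizes give the binomial checks 3-sigma windows of a few percent while
each suite completes in seconds to a couple of minutes on one CPU. Exact
assertions (oracle equivalence, partition conservation, ground-truth
recovery) use equality or 1e-12 absolute slack; registration recovery uses
1e-9 on exact correspondences; stochastic recoveries use 3-sigma binomial
windows derived from the generator's own effective n.

## Known limitations

- Registration quality on real images depends on the operator's control
  points; only the fitting, not point selection, is covered here.
- The SPA/SDA statistics are purely areal; no statistical testing across
  samples is included (reports are exported tidy for external stats).
- The Leiden partition of the quality network depends on k and resolution;
  on small homogeneous datasets single-cluster partitions are common and no
  cell is flagged, which is the intended conservative behavior.
- The specificity score ignores expression magnitude by design; a gene can
  rank highly at modest absolute expression.
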