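# duraquant

Quantitative pipelines for studying early-life B lymphopoiesis in the dura
mater — the outermost meningeal layer, which in neonatal mice hosts
developing B cells clustered around the dural venous sinuses.

The package implements three analysis tracks, each exercisable end-to-end
on synthetic data with exact ground truth (no downloads required):

1. **Spatial quantification** (`duraquant.spatial`) — register whole-mount
   tile scans to a common sinus reference via control-point affines,
   binarize signal channels at batch-consistent thresholds, build per-pixel
   mean heatmaps across mice, partition the tissue into the
   **sinus-proximal area** (SPA: sinus plus everything within 300 um of its
   edge, by Euclidean distance transform) and the **sinus-distal area**
   (SDA), and report per region the percent occupied by signal and the
   percent of total signal contained:

   coverage%(R) = 100 |S ∩ R| / |R|,  signal-fraction%(R) = 100 |S ∩ R| / |S|

2. **Clonal lineage statistics** (`duraquant.clonal`) — CARLIN barcode
   allele-table analytics: drop the unedited allele 0 and alleles with
   total UMI < 2, then compute UMI-weighted sharing percentages
   (multi-organ, pairwise, exclusive), top-k expanded clone profiles, and
   top-300 log2(UMI + 1) heatmap matrices. For organ a,

   multi-organ%(a) = 100 Σ_{alleles shared with ≥1 other organ} UMI_a / Σ UMI_a

3. **Single-cell QC and marker specificity** (`duraquant.markers`) —
   eight-metric quality network (SNN graph + Leiden communities, outlier
   communities flagged at |median z| > 2), strict hard filters (> 500
   genes, 0% < mito < 10%), Wilcoxon rank-sum DE with BH adjustment, and
   marker ranking by

   specificity(g) = pct_expressing_target(g) / pct_expressing_comparator(g)

   after filtering at log2FC ≥ 0.585, padj ≤ 0.05, pct_target ≥ 70%.

`duraquant.synth` generates all three input kinds — sinus-shaped landmark
geometry with proximally enriched signal, multi-organ clone seeding with a
tunable sharing probability, and expression matrices with planted markers
and a planted low-quality subpopulation — deterministically from a seed,
with ground truth returned alongside.

## Worked example

```python
from duraquant import spatial, clonal, synth

# --- spatial: simulate a whole mount with 90% of B-cell signal near sinuses
img, truth = synth.simulate_whole_mount(synth.ImageSimConfig(proximal_fraction=0.9, seed=1))
bc = spatial.BinarizationConfig("batch1", {"landmark": 0.5, "signal": 0.5})
sinus = spatial.binarize_channel(img.channels["landmark"], "landmark", bc)
signal = spatial.binarize_channel(img.channels["signal"], "signal", bc)
part = spatial.segment_regions(sinus, dilation_um=300, pixel_size=img.pixel_size)
print(spatial.compute_coverage(signal, part)[["region", "coverage_pct", "signal_fraction_pct"]])
#   region  coverage_pct  signal_fraction_pct
# 0    SPA      3.730023            96.666667
# 1    SDA      0.116154             3.333333

# --- clonal: high multi-organ seeding mimics embryonic barcode induction
table, truth = synth.simulate_allele_tables(synth.CloneSimConfig(p_multiorgan=0.9, seed=1))
ft = clonal.filter_alleles(table)
print(round(clonal.multi_organ_sharing(ft, "dura"), 2), round(truth["true_sharing"]["dura"], 2))
# 96.51 96.51
```

The SPA holds 96.7% of the signal (29 of the 30 simulated B-cell clusters
landed in the proximal band, binomial around the configured 90%), and its
coverage is an order of magnitude above the SDA's. The computed dural
multi-organ sharing equals the value enumerated from the simulator's
founder map exactly, because the statistic is a deterministic function of
the allele table.

The `analysis/` scripts run the same pipelines as narrative studies —
sinus-enriched vs unenriched imaging groups (`01`), clone sharing across
embryonic-to-postnatal induction regimes (`02`), and QC plus marker
ranking with Foxd1-like / Col3a1-like planted genes (`03`) — writing tidy
tables under `results/`. A `duraquant` CLI exposes the shell-level steps
(`duraquant spatial coverage`, `duraquant clonal share`,
`duraquant markers rank`, ...).

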