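"""Whole-mount B-cell localization relative to the dural sinuses.

Simulates two groups of dural whole mounts — one with B-cell signal
enriched near the sinuses (90% of signal within the 300 um sinus-proximal
band) and one with uniform-like placement (50%) — then runs the full
quantification: binarization at the batch threshold, SPA/SDA segmentation,
per-group aggregate heatmaps, and per-sample coverage statistics.

Writes results/spatial_coverage.csv and results/heatmap_<group>.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from duraquant import spatial
from duraquant.synth import ImageSimConfig, simulate_whole_mount

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_PER_GROUP = 6
GROUPS = {"sinus_enriched": 0.9, "unenriched": 0.5}


def main(seed: int = 0) -> pd.DataFrame:
    RESULTS.mkdir(exist_ok=True)
    bc = spatial.BinarizationConfig("batch1", {"landmark": 0.5, "signal": 0.5})
    reports = []
    for group, p in GROUPS.items():
        masks = []
        for i in range(N_PER_GROUP):
            cfg = ImageSimConfig(proximal_fraction=p, seed=seed * 1000 + i)
            img, _ = simulate_whole_mount(cfg)
            sinus = spatial.binarize_channel(img.channels["landmark"], "landmark", bc)
            sig = spatial.binarize_channel(img.channels["signal"], "signal", bc)
            part = spatial.segment_regions(
                sinus, dilation_um=cfg.dilation_um, pixel_size=cfg.pixel_size
            )
            rep = spatial.compute_coverage(sig, part, sample_id=f"{group}-{i}")
            rep["group"] = group
            reports.append(rep)
            masks.append(sig)
        hm = spatial.aggregate_heatmap(masks, group=group)
        pd.DataFrame(hm.mean).to_csv(
            RESULTS / f"heatmap_{group}.csv", index=False, header=False
        )
    out = pd.concat(reports, ignore_index=True)
    out.to_csv(RESULTS / "spatial_coverage.csv", index=False)

    summary = out.groupby(["group", "region"])["signal_fraction_pct"].mean()
    print("Mean percent of total B-cell signal per region:")
    print(summary.round(2).to_string())
    print(
        "\nSinus-proximal enrichment is recovered: the enriched group places "
        f"{summary[('sinus_enriched', 'SPA')]:.1f}% of signal in the SPA vs "
        f"{summary[('unenriched', 'SPA')]:.1f}% for the unenriched group."
    )
    return out


if __name__ == "__main__":
    main()
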