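"""Quality-network cell QC and dural-FLC marker specificity ranking.

Simulates a single-cell count matrix with a dural fibroblast-like cell
(FLC) group and a comparator non-immune group, a planted low-quality
subpopulation, and planted markers of graded specificity (a Foxd1-like
gene: high in FLCs, nearly absent elsewhere; a Col3a1-like pan-fibroblast
gene: high everywhere). Runs the eight-metric quality network + hard
filters, then Wilcoxon DE, percent-expressing, and specificity ranking on
the cleaned cells.

Writes results/qc_summary.csv and results/specificity_table.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from duraquant import markers
from duraquant.synth import ExprSimConfig, LowQualitySpec, MarkerSpec, simulate_expression

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> pd.DataFrame:
    RESULTS.mkdir(exist_ok=True)
    cfg = ExprSimConfig(
        group_sizes={"FLC": 300, "other_nonimmune": 300},
        n_genes=200,
        markers=[
            MarkerSpec(gene="Foxd1like", group="FLC", pct_in=90, pct_out=2, mean_expr=6),
            MarkerSpec(gene="Shisa3like", group="FLC", pct_in=80, pct_out=8, mean_expr=5),
            MarkerSpec(gene="Col3a1like", group="FLC", pct_in=95, pct_out=60, mean_expr=8),
        ],
        low_quality=LowQualitySpec(n_cells=60, mito_fraction=0.5),
        seed=seed,
    )
    adata, truth = simulate_expression(cfg)

    metrics = markers.compute_quality_metrics(adata, truth["gene_sets"])
    flagged, clusters = markers.flag_low_quality_clusters(metrics)
    lq = adata.obs["is_low_quality"].to_numpy()
    sens = (flagged & lq).sum() / lq.sum()
    spec = (~flagged & ~lq).sum() / (~lq).sum()
    clusters.to_csv(RESULTS / "qc_summary.csv", index=False)
    print(
        f"Quality network: flagged {flagged.sum()} of {len(flagged)} cells "
        f"(sensitivity {sens:.3f}, specificity {spec:.3f} against planted truth)"
    )

    clean = adata[~flagged].copy()
    clean.var["mito"] = clean.var_names.isin(truth["gene_sets"]["mito"])
    keep = markers.hard_filter_cells(
        clean, markers.CellFilterConfig(min_genes=50)  # small synthetic panel
    )
    clean = clean[keep].copy()
    print(f"Hard filters keep {clean.n_obs} cells")

    t = (clean.obs["group"] == "FLC").to_numpy()
    c = (clean.obs["group"] == "other_nonimmune").to_numpy()
    de = markers.wilcoxon_de(clean, t, c)
    pct = markers.percent_expressing_table(clean, t, c)
    table = markers.specificity_rank(de, pct, n_comparator=int(c.sum()))
    table.to_csv(RESULTS / "specificity_table.csv")

    top = table[table["passes"]].head(5)
    print("\nTop specificity-ranked FLC marker candidates:")
    print(
        top[["pct_target", "pct_comparator", "specificity", "log2fc", "rank"]]
        .round(3)
        .to_string()
    )
    print(
        "\nThe Foxd1-like planted marker ranks "
        f"{int(table.loc['Foxd1like', 'rank'])}; the pan-fibroblast Col3a1-like "
        "gene passes DE but ranks "
        f"{int(table.loc['Col3a1like', 'rank'])} because the comparator also "
        "expresses it — specificity, not expression level, drives the ranking."
    )
    return table


if __name__ == "__main__":
    main()
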