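"""Clone sharing across organs under early vs late barcode induction.

Simulates CARLIN allele tables for three induction regimes — embryonic
induction with high multi-organ seeding (p = 0.9), intermediate (0.5), and
postnatal with mostly organ-private clones (0.1) — for several mice each,
then computes UMI-weighted multi-organ / pairwise / exclusive sharing, the
dura's top-5 expanded clones, and the top-300 log2 heatmap matrix.

Writes results/clonal_sharing.csv, results/top5_dura.csv and
results/clonal_heatmap_<regime>.csv.
"""

from pathlib import Path

import pandas as pd

from duraquant import clonal
from duraquant.synth import CloneSimConfig, simulate_allele_tables

RESULTS = Path(__file__).resolve().parents[1] / "results"
REGIMES = {"iE12.5-like": 0.9, "iE17.5-like": 0.5, "iP3-like": 0.1}
N_MICE = 4


def main(seed: int = 0) -> pd.DataFrame:
    RESULTS.mkdir(exist_ok=True)
    all_sharing, top5 = [], []
    for regime, p in REGIMES.items():
        for mouse in range(N_MICE):
            table, _ = simulate_allele_tables(
                CloneSimConfig(
                    n_clones=2000, p_multiorgan=p, seed=seed * 100 + mouse,
                    mouse_id=f"{regime}-m{mouse}", induction=regime,
                )
            )
            ft = clonal.filter_alleles(table)
            s = clonal.sharing_summary(ft)
            s["induction"] = regime
            s["mouse"] = table.mouse_id
            all_sharing.append(s)
            t5 = clonal.top_expanded(ft, "dura", k=5)
            t5["induction"] = regime
            t5["mouse"] = table.mouse_id
            top5.append(t5)
            if mouse == 0:
                clonal.heatmap_matrix(ft, top_n=300).to_csv(
                    RESULTS / f"clonal_heatmap_{regime}.csv"
                )
    sharing = pd.concat(all_sharing, ignore_index=True)
    sharing.to_csv(RESULTS / "clonal_sharing.csv", index=False)
    pd.concat(top5, ignore_index=True).to_csv(RESULTS / "top5_dura.csv", index=False)

    multi = (
        sharing[sharing["statistic"] == "multi_organ"]
        .groupby(["induction", "organ"])["sharing_pct"]
        .mean()
        .unstack()
    )
    print("Mean multi-organ barcode sharing (% of organ UMIs) by induction regime:")
    print(multi.round(1).to_string())
    dura = multi["dura"]
    print(
        "\nDural sharing falls from "
        f"{dura['iE12.5-like']:.1f}% (embryonic-like induction) to "
        f"{dura['iP3-like']:.1f}% (postnatal-like), the signature of a "
        "progenitor pool that stops migrating systemically around birth."
    )
    return sharing


if __name__ == "__main__":
    main()
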