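"""CARLIN allele-table analytics.

An allele table records, for one mouse, how many UMIs of each edited CARLIN
barcode allele were recovered from B cells in each sampled organ (dura,
calvarial bone marrow, leg bone marrow, spleen). Because the barcode is
transcribed, UMI counts proxy cell numbers, so UMI-weighted statistics over
shared allele sequences estimate what fraction of an organ's B cells derive
from progenitor clones that also contributed to other organs.

Filtering (once, before any statistic): allele 0 is the unedited locus and
is dropped; alleles with a total UMI count below two across all organs of
the mouse are dropped.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

UNEDITED_ALLELE_ID = 0
MIN_TOTAL_UMI = 2


@dataclass
class AlleleTable:
    """Alleles x organs UMI-count matrix for a single mouse.

    ``counts`` is indexed by a (allele_id, allele_seq) MultiIndex with one
    integer column per organ, in sampling order.
    """

    counts: pd.DataFrame
    mouse_id: str = ""
    induction: str = ""
    filtered: bool = False

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 1:
            raise ValueError("allele table needs at least one organ column")
        if list(self.counts.index.names) != ["allele_id", "allele_seq"]:
            raise ValueError("counts must be indexed by (allele_id, allele_seq)")
        vals = self.counts.to_numpy()
        if vals.size and (np.any(vals < 0) or not np.issubdtype(vals.dtype, np.integer)):
            raise ValueError("UMI counts must be non-negative integers")
        ids = self.counts.index.get_level_values("allele_id")
        seqs = self.counts.index.get_level_values("allele_seq")
        if pd.Series(seqs).groupby(np.asarray(ids)).nunique().gt(1).any():
            raise ValueError("allele_seq must be unique per allele_id")
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate allele_seq rows; collapse counts first")

    @property
    def organs(self) -> list[str]:
        return list(self.counts.columns)

    def organ_total(self, organ: str) -> int:
        return int(self.counts[organ].sum())

    @classmethod
    def from_long(
        cls, long: pd.DataFrame, mouse_id: str = "", induction: str = ""
    ) -> "AlleleTable":
        """Build from tidy rows ``allele_id, allele_seq, organ, umi_count``."""
        wide = (
            long.pivot_table(
                index=["allele_id", "allele_seq"],
                columns="organ",
                values="umi_count",
                aggfunc="sum",
                fill_value=0,
            )
            .astype(int)
        )
        # preserve first-appearance organ order from the tidy table
        order = list(dict.fromkeys(long["organ"]))
        wide = wide[order]
        wide.columns.name = None
        return cls(counts=wide, mouse_id=mouse_id, induction=induction)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("umi_count")
            .reset_index()
            .rename(columns={"level_2": "organ"})
        )
        long.columns = ["allele_id", "allele_seq", "organ", "umi_count"]
        return long[long["umi_count"] > 0].reset_index(drop=True)


def filter_alleles(table: AlleleTable) -> AlleleTable:
    """Drop the unedited allele (id 0) and alleles with total UMI < 2."""
    counts = table.counts
    ids = counts.index.get_level_values("allele_id")
    keep = (ids != UNEDITED_ALLELE_ID) & (counts.sum(axis=1) >= MIN_TOTAL_UMI)
    return replace(table, counts=counts.loc[keep], filtered=True)


def _require_filtered(table: AlleleTable, allow_unfiltered: bool) -> None:
    if not table.filtered and not allow_unfiltered:
        raise ValueError(
            "sharing statistics are defined on filtered tables; call "
            "filter_alleles first or pass allow_unfiltered=True"
        )


def _weights(table: AlleleTable, organ: str, umi_weighted: bool) -> pd.Series:
    col = table.counts[organ]
    return col if umi_weighted else (col > 0).astype(int)


def multi_organ_sharing(
    table: AlleleTable,
    organ: str,
    *,
    umi_weighted: bool = True,
    allow_unfiltered: bool = False,
) -> float:
    """Percent of an organ's barcode UMIs shared with at least one other organ.

    100 * (UMIs in ``organ`` on alleles also present, count > 0, in >= 1
    other organ) / (all UMIs in ``organ``). Allele identity is exact
    allele-sequence match. ``umi_weighted=False`` switches to counting
    alleles instead of UMIs (sensitivity variant).
    """
    _require_filtered(table, allow_unfiltered)
    if organ not in table.organs:
        raise KeyError(organ)
    w = _weights(table, organ, umi_weighted)
    total = w.sum()
    if total == 0:
        warnings.warn(f"organ {organ!r} has zero UMIs; sharing undefined", stacklevel=2)
        return float("nan")
    others = [o for o in table.organs if o != organ]
    shared = (table.counts[others] > 0).any(axis=1) if others else pd.Series(False, index=w.index)
    return 100.0 * float(w[shared & (table.counts[organ] > 0)].sum()) / float(total)


def pairwise_sharing(
    table: AlleleTable,
    organ_a: str,
    organ_b: str,
    *,
    umi_weighted: bool = True,
    allow_unfiltered: bool = False,
) -> float:
    """Percent of organ a's UMIs on alleles also present in organ b.

    Asymmetric by design: the denominator is organ a's total UMIs.
    """
    _require_filtered(table, allow_unfiltered)
    if organ_a == organ_b:
        raise ValueError("pairwise sharing requires two distinct organs")
    for o in (organ_a, organ_b):
        if o not in table.organs:
            raise KeyError(o)
    w = _weights(table, organ_a, umi_weighted)
    total = w.sum()
    if total == 0:
        warnings.warn(f"organ {organ_a!r} has zero UMIs; sharing undefined", stacklevel=2)
        return float("nan")
    in_b = table.counts[organ_b] > 0
    return 100.0 * float(w[in_b & (table.counts[organ_a] > 0)].sum()) / float(total)


def exclusive_sharing(
    table: AlleleTable,
    organ_a: str,
    organ_b: str,
    *,
    umi_weighted: bool = True,
    allow_unfiltered: bool = False,
) -> float:
    """Percent of organ a's UMIs shared with organ b and with no other organ."""
    _require_filtered(table, allow_unfiltered)
    if organ_a == organ_b:
        raise ValueError("exclusive sharing requires two distinct organs")
    for o in (organ_a, organ_b):
        if o not in table.organs:
            raise KeyError(o)
    w = _weights(table, organ_a, umi_weighted)
    total = w.sum()
    if total == 0:
        warnings.warn(f"organ {organ_a!r} has zero UMIs; sharing undefined", stacklevel=2)
        return float("nan")
    others = [o for o in table.organs if o not in (organ_a, organ_b)]
    in_b = table.counts[organ_b] > 0
    nowhere_else = (
        ~(table.counts[others] > 0).any(axis=1)
        if others
        else pd.Series(True, index=w.index)
    )
    sel = in_b & nowhere_else & (table.counts[organ_a] > 0)
    return 100.0 * float(w[sel].sum()) / float(total)


def sharing_summary(
    table: AlleleTable, *, umi_weighted: bool = True, allow_unfiltered: bool = False
) -> pd.DataFrame:
    """Tidy summary of multi-organ, pairwise, and exclusive sharing.

    One row per (organ, statistic): multi-organ sharing per organ and, for
    every ordered organ pair (a, b), pairwise and exclusive sharing with
    organ a as the denominator.
    """
    kw = dict(umi_weighted=umi_weighted, allow_unfiltered=allow_unfiltered)
    rows = []
    for organ in table.organs:
        rows.append(
            {
                "organ": organ,
                "other": "",
                "statistic": "multi_organ",
                "sharing_pct": multi_organ_sharing(table, organ, **kw),
                "denominator_umis": table.organ_total(organ),
            }
        )
    for a, b in itertools.permutations(table.organs, 2):
        rows.append(
            {
                "organ": a,
                "other": b,
                "statistic": "pairwise",
                "sharing_pct": pairwise_sharing(table, a, b, **kw),
                "denominator_umis": table.organ_total(a),
            }
        )
        rows.append(
            {
                "organ": a,
                "other": b,
                "statistic": "exclusive",
                "sharing_pct": exclusive_sharing(table, a, b, **kw),
                "denominator_umis": table.organ_total(a),
            }
        )
    return pd.DataFrame(rows)


def top_expanded(
    table: AlleleTable, organ: str, k: int = 5, *, allow_unfiltered: bool = False
) -> pd.DataFrame:
    """Top-k expanded alleles in one organ with cross-organ presence flags.

    Sorted by the organ's UMI count descending, ties broken by allele_id
    ascending. ``fraction`` is each allele's share of the organ total; the
    ``in_<organ>`` columns flag which other organs carry the same allele
    (the donut-plot highlight of the dura's top clones elsewhere).
    """
    _require_filtered(table, allow_unfiltered)
    if organ not in table.organs:
        raise KeyError(organ)
    counts = table.counts
    ids = counts.index.get_level_values("allele_id")
    order = np.lexsort((np.asarray(ids), -counts[organ].to_numpy()))
    top = counts.iloc[order[: max(k, 0)]]
    top = top[top[organ] > 0] if len(top) else top
    total = table.organ_total(organ)
    out = pd.DataFrame(
        {
            "allele_id": top.index.get_level_values("allele_id"),
            "allele_seq": top.index.get_level_values("allele_seq"),
            "umi_count": top[organ].to_numpy(),
            "fraction": top[organ].to_numpy() / total if total > 0 else np.nan,
        }
    )
    for other in table.organs:
        if other != organ:
            out[f"in_{other}"] = (top[other] > 0).to_numpy()
    return out.reset_index(drop=True)


def heatmap_matrix(
    table: AlleleTable,
    top_n: int = 300,
    *,
    per_tissue: bool = True,
    allow_unfiltered: bool = False,
) -> pd.DataFrame:
    """log2(UMI + 1) matrix of the top alleles for heatmap display.

    Rows are the union over organs of each organ's ``top_n`` alleles by that
    organ's count (``per_tissue=False`` uses a single global top-``top_n`` by
    max count instead), ordered by max count across organs descending, ties
    by allele_id ascending. Zero counts map to 0 exactly.
    """
    _require_filtered(table, allow_unfiltered)
    counts = table.counts
    ids = counts.index.get_level_values("allele_id").to_numpy()
    if per_tissue:
        selected = np.zeros(len(counts), dtype=bool)
        for organ in table.organs:
            col = counts[organ].to_numpy()
            order = np.lexsort((ids, -col))
            keep = order[: min(top_n, len(order))]
            selected[keep[col[keep] > 0]] = True
    else:
        mx = counts.to_numpy().max(axis=1)
        order = np.lexsort((ids, -mx))
        keep = order[: min(top_n, len(order))]
        selected = np.zeros(len(counts), dtype=bool)
        selected[keep[mx[keep] > 0]] = True
    sub = counts.loc[selected]
    sub_ids = sub.index.get_level_values("allele_id").to_numpy()
    row_order = np.lexsort((sub_ids, -sub.to_numpy().max(axis=1, initial=0)))
    sub = sub.iloc[row_order]
    mat = np.log2(sub.to_numpy(dtype=float) + 1.0)
    return pd.DataFrame(mat, index=sub.index.get_level_values("allele_id"), columns=sub.columns)
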