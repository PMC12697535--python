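"""Single-cell quality control and marker-specificity scoring.

Two procedures operating on an AnnData of raw counts:

1. Quality-network cell QC — eight per-cell quality metrics (gene-set
   expression fractions for OXPHOS / mitochondrial / ribosomal /
   immediate-early genes, percent of RNA in the top-50 genes and in lncRNAs,
   log2 unique genes and UMIs) are z-scored, a shared-nearest-neighbor graph
   is built over metric space, communities are detected, and communities
   with an outlier metric distribution are flagged for removal; followed by
   hard filters (> 500 genes, 0% < mito < 10%, all strict).

2. Marker specificity — Wilcoxon rank-sum differential expression of a
   target population (dural fibroblast-like cells) against a comparator,
   Benjamini-Hochberg adjustment, then filtering (log2FC >= 0.585,
   padj <= 0.05, expressed in >= 70% of the target) and ranking by
   specificity = pct_expressing_target / pct_expressing_comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

QC_METRICS = [
    "pct_oxphos",
    "pct_mito",
    "pct_ribo",
    "pct_ieg",
    "pct_top50",
    "pct_lnc",
    "log2_genes",
    "log2_umis",
]


@dataclass
class CellFilterConfig:
    """Hard per-cell filters; all bounds are strict inequalities."""

    min_genes: int = 500
    mito_lower: float = 0.0
    mito_upper: float = 10.0
    require_nonzero_mito: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.mito_lower < self.mito_upper <= 100):
            raise ValueError("need 0 <= mito_lower < mito_upper <= 100")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")


@dataclass
class MarkerFilterConfig:
    min_pct_target: float = 70.0
    max_padj: float = 0.05
    min_log2fc: float = 0.585

    def __post_init__(self) -> None:
        if not 0 <= self.min_pct_target <= 100:
            raise ValueError("min_pct_target must be in [0, 100]")
        if not 0 < self.max_padj <= 1:
            raise ValueError("max_padj must be in (0, 1]")


@dataclass
class QualityGraphConfig:
    """Shared-nearest-neighbor graph over z-scored quality-metric space."""

    k: int = 20
    resolution: float = 1.0
    outlier_z: float = 2.0
    seed: int = 0


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def _counts(adata: AnnData) -> np.ndarray:
    return _dense(adata.X).astype(float)


def hard_filter_cells(adata: AnnData, config: CellFilterConfig | None = None) -> np.ndarray:
    """Boolean keep-mask: genes_detected > min_genes and mito% strictly inside bounds.

    Mitochondrial genes are taken from a boolean ``adata.var["mito"]`` column
    or, failing that, a "mt-" gene-name prefix. Cells with exactly zero
    mitochondrial reads are removed (the lower bound is strict); set
    ``require_nonzero_mito=False`` to disable that arm.
    """
    config = config or CellFilterConfig()
    if "mito" in adata.var:
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    else:
        mito_mask = np.array([n.lower().startswith("mt-") for n in adata.var_names])
    if not mito_mask.any():
        raise ValueError(
            "no mitochondrial genes annotated (var['mito'] or 'mt-' prefix); "
            "the mito-fraction filter is undefined"
        )
    X = _counts(adata)
    genes_detected = (X > 0).sum(axis=1)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cells with zero total UMIs must be removed upstream")
    mito_pct = 100.0 * X[:, mito_mask].sum(axis=1) / totals
    keep = (genes_detected > config.min_genes) & (mito_pct < config.mito_upper)
    if config.require_nonzero_mito:
        keep &= mito_pct > config.mito_lower
    else:
        keep &= mito_pct >= config.mito_lower
    return keep


def compute_quality_metrics(
    adata: AnnData, gene_sets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Eight per-cell quality metrics.

    ``gene_sets`` must provide gene-name lists under the keys ``oxphos``,
    ``mito``, ``ribo``, ``ieg`` and ``lnc`` (annotation lists are supplied by
    the user; no ontology is bundled). Set-fraction metrics are
    100 * (UMIs in set) / (total UMIs); ``pct_top50`` uses each cell's own 50
    highest-count genes; the last two are log2 of distinct expressed genes
    and of total UMIs.
    """
    required = {"oxphos", "mito", "ribo", "ieg", "lnc"}
    missing = required - set(gene_sets)
    if missing:
        raise KeyError(f"gene_sets missing {sorted(missing)}")
    X = _counts(adata)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cells with zero total UMIs must be removed upstream")
    names = pd.Index(adata.var_names)
    out = {}
    for key, col in [("oxphos", "pct_oxphos"), ("mito", "pct_mito"),
                     ("ribo", "pct_ribo"), ("ieg", "pct_ieg"), ("lnc", "pct_lnc")]:
        mask = names.isin(gene_sets[key])
        out[col] = 100.0 * X[:, mask].sum(axis=1) / totals
    k = min(50, X.shape[1])
    part = np.partition(X, X.shape[1] - k, axis=1)[:, X.shape[1] - k:]
    out["pct_top50"] = 100.0 * part.sum(axis=1) / totals
    out["log2_genes"] = np.log2((X > 0).sum(axis=1))
    out["log2_umis"] = np.log2(totals)
    df = pd.DataFrame(out, index=adata.obs_names)[QC_METRICS]
    return df


def _snn_graph(z: np.ndarray, k: int) -> ig.Graph:
    n = z.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    _, idx = nn.kneighbors(z)
    neigh = [set(row) for row in idx]  # includes self, as Seurat's SNN does
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w > 0:
                edges.append((i, j))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def flag_low_quality_clusters(
    metrics: pd.DataFrame, config: QualityGraphConfig | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag cells in quality-network communities with outlier metrics.

    Metrics are z-scored per column; a Jaccard-weighted SNN graph over the
    k nearest neighbors in metric space is clustered with Leiden (modularity,
    configurable resolution); a community is flagged iff the absolute value
    of its median z exceeds ``outlier_z`` on at least one metric.

    Returns ``(flagged, clusters)`` where ``flagged`` is a per-cell boolean
    array and ``clusters`` summarizes each community (size, flagged,
    triggering metrics).
    """
    config = config or QualityGraphConfig()
    n = len(metrics)
    if n < 2:
        raise ValueError("need at least 2 cells to build a quality network")
    vals = metrics[QC_METRICS].to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - vals.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    k = config.k
    if k >= n:
        k = n - 1
        warnings.warn(f"fewer cells than k; reduced k to {k}", stacklevel=2)
    g = _snn_graph(z, k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=config.resolution,
        seed=config.seed,
    )
    labels = np.asarray(part.membership)
    flagged = np.zeros(n, dtype=bool)
    rows = []
    for c in np.unique(labels):
        members = labels == c
        med = np.median(z[members], axis=0)
        trigger = [m for m, v in zip(QC_METRICS, med) if abs(v) > config.outlier_z]
        if trigger:
            flagged[members] = True
        rows.append(
            {
                "cluster": int(c),
                "n_cells": int(members.sum()),
                "flagged": bool(trigger),
                "triggering_metrics": ";".join(trigger),
                **{f"median_z_{m}": v for m, v in zip(QC_METRICS, med)},
            }
        )
    return flagged, pd.DataFrame(rows)


def percent_expressing(adata: AnnData, cells: np.ndarray, gene: str) -> float:
    """Percent of the given cells with count > 0 for one gene."""
    cells = np.asarray(cells)
    if cells.dtype == bool:
        n = int(cells.sum())
    else:
        n = len(cells)
    if n == 0:
        raise ValueError("empty cell group")
    col = _dense(adata[cells, gene].X).ravel()
    return 100.0 * float((col > 0).sum()) / n


def percent_expressing_table(
    adata: AnnData, target: np.ndarray, comparator: np.ndarray
) -> pd.DataFrame:
    """Per-gene percent-expressing in target and comparator cell sets."""
    target = np.asarray(target, dtype=bool)
    comparator = np.asarray(comparator, dtype=bool)
    if target.sum() == 0 or comparator.sum() == 0:
        raise ValueError("empty cell group")
    X = _counts(adata)
    pct_t = 100.0 * (X[target] > 0).sum(axis=0) / target.sum()
    pct_c = 100.0 * (X[comparator] > 0).sum(axis=0) / comparator.sum()
    return pd.DataFrame(
        {"gene": adata.var_names, "pct_target": pct_t, "pct_comparator": pct_c}
    ).set_index("gene")


def normalize_log1p(X, target_sum: float | None = None) -> np.ndarray:
    """Per-cell scaling to a common total (median library size) then log1p."""
    X = _dense(X).astype(float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cells with zero total UMIs must be removed upstream")
    if target_sum is None:
        target_sum = float(np.median(totals))
    return np.log1p(X / totals[:, None] * target_sum)


def wilcoxon_de(
    adata: AnnData, target: np.ndarray, comparator: np.ndarray
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE of target vs comparator.

    Expression is log-normalized (per-cell scaling to the median library
    size, then log1p). P-values are Benjamini-Hochberg adjusted across all
    genes tested. ``log2fc`` is log2(mean_target + 1) - log2(mean_comp + 1)
    on the linear normalized scale, so 0.585 corresponds to a 1.5-fold
    change in (shifted) group means. Genes constant across both groups get
    p = 1 by convention.
    """
    target = np.asarray(target, dtype=bool)
    comparator = np.asarray(comparator, dtype=bool)
    if target.sum() < 2 or comparator.sum() < 2:
        raise ValueError("both groups need at least 2 cells")
    if np.any(target & comparator):
        raise ValueError("target and comparator groups overlap")
    norm = normalize_log1p(adata.X)
    xt, xc = norm[target], norm[comparator]
    lin_t, lin_c = np.expm1(xt).mean(axis=0), np.expm1(xc).mean(axis=0)
    log2fc = np.log2(lin_t + 1.0) - np.log2(lin_c + 1.0)
    n_genes = norm.shape[1]
    const = np.array(
        [np.ptp(np.concatenate([xt[:, g], xc[:, g]])) == 0 for g in range(n_genes)]
    )
    stat = np.full(n_genes, np.nan)
    pval = np.ones(n_genes)
    if (~const).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                xt[:, ~const], xc[:, ~const], axis=0, alternative="two-sided",
                method="auto",
            )
        stat[~const] = res.statistic
        pval[~const] = np.nan_to_num(res.pvalue, nan=1.0)
    stat[const] = target.sum() * comparator.sum() / 2.0
    padj = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "statistic": stat,
            "pval": pval,
            "padj": padj,
            "log2fc": log2fc,
        }
    ).set_index("gene")


def specificity_rank(
    de: pd.DataFrame,
    pct: pd.DataFrame,
    n_comparator: int,
    config: MarkerFilterConfig | None = None,
) -> pd.DataFrame:
    """Filter DE genes and rank them by target-vs-comparator specificity.

    A gene passes when log2fc >= min_log2fc, padj <= max_padj and
    pct_target >= min_pct_target (all conjunctive). Specificity is
    pct_target / pct_comparator; when no comparator cell expresses the gene,
    pct_comparator is floored at the percent equivalent of one comparator
    cell (100 / n_comparator) so the score stays finite (``floored`` column
    marks those genes). Passing genes are ranked 1..n by specificity
    descending, ties by pct_target descending then gene name.
    """
    config = config or MarkerFilterConfig()
    if not de.index.equals(pct.index):
        pct = pct.reindex(de.index)
        if pct.isna().any().any():
            raise ValueError("de and pct tables must cover the same genes")
    if n_comparator < 1:
        raise ValueError("n_comparator must be >= 1")
    out = de.join(pct)
    out["pass_log2fc"] = out["log2fc"] >= config.min_log2fc
    out["pass_padj"] = out["padj"] <= config.max_padj
    out["pass_pct"] = out["pct_target"] >= config.min_pct_target
    out["passes"] = out["pass_log2fc"] & out["pass_padj"] & out["pass_pct"]
    floor = 100.0 / n_comparator
    out["floored"] = out["pct_comparator"] <= 0
    denom = np.where(out["floored"], floor, out["pct_comparator"])
    out["specificity"] = out["pct_target"] / denom
    out["log2_specificity"] = np.log2(out["specificity"].where(out["specificity"] > 0))
    # rank passing genes: specificity desc, pct_target desc, gene name asc
    # (stable mergesort over a name-sorted frame yields the name tie-break)
    passing = out[out["passes"]].sort_index().sort_values(
        ["specificity", "pct_target"], ascending=[False, False], kind="mergesort"
    )
    out["rank"] = pd.Series(
        np.arange(1, len(passing) + 1, dtype=float), index=passing.index
    ).reindex(out.index)
    return out.sort_values(["passes", "rank"], ascending=[False, True], na_position="last")
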