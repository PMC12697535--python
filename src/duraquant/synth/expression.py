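"""Synthetic single-cell count matrices with planted structure.

Generates an AnnData of raw UMI counts with labeled cell groups, planted
group-specific marker genes at controlled percent-expressing, gene-set
annotations (mitochondrial, ribosomal, OXPHOS, immediate-early, lncRNA)
driving the eight QC metrics, and an optional planted low-quality
subpopulation with elevated mitochondrial fraction and reduced gene
detection. Background counts follow a Poisson-lognormal: per-gene lognormal
means, per-cell lognormal library factors, Poisson sampling — simple
overdispersion, sufficient for threshold statistics like percent-expressing
and the QC metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse


@dataclass
class MarkerSpec:
    """A planted marker: expressed in ``pct_in`` % of ``group`` cells and
    ``pct_out`` % of all other cells, with mean count ``mean_expr`` when on."""

    gene: str
    group: str
    pct_in: float = 90.0
    pct_out: float = 5.0
    mean_expr: float = 5.0

    def __post_init__(self) -> None:
        for p in (self.pct_in, self.pct_out):
            if not 0.0 <= p <= 100.0:
                raise ValueError("percent-expressing targets must be in [0, 100]")
        if self.mean_expr < 1:
            raise ValueError("mean_expr must be >= 1")


@dataclass
class LowQualitySpec:
    """Planted low-quality cells: mito fraction recentered, genes dropped."""

    n_cells: int = 50
    mito_fraction: float = 0.5
    gene_keep_prob: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.mito_fraction < 1.0:
            raise ValueError("mito_fraction must be in (0, 1)")
        if not 0.0 < self.gene_keep_prob <= 1.0:
            raise ValueError("gene_keep_prob must be in (0, 1]")


@dataclass
class ExprSimConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"FLC": 300, "other_nonimmune": 300}
    )
    n_genes: int = 200
    markers: list[MarkerSpec] = field(default_factory=list)
    base_expr_rate: float = 0.5  # P(background gene expressed in a cell)
    base_mean: float = 2.0
    gene_log_sigma: float = 0.5
    lib_log_sigma: float = 0.3
    n_mito: int = 10
    n_ribo: int = 20
    n_oxphos: int = 20
    n_ieg: int = 10
    n_lnc: int = 15
    mito_base_fraction: float = 0.05
    low_quality: LowQualitySpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        n_special = self.n_mito + self.n_ribo + self.n_oxphos + self.n_ieg + self.n_lnc
        if n_special + len(self.markers) > self.n_genes:
            raise ValueError("n_genes too small for gene sets plus markers")
        groups = set(self.group_sizes)
        for m in self.markers:
            if m.group not in groups:
                raise ValueError(f"marker {m.gene!r} references unknown group {m.group!r}")
        names = [m.gene for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker gene names must be unique")
        if self.low_quality is not None and self.low_quality.n_cells >= sum(
            self.group_sizes.values()
        ):
            raise ValueError("low-quality subpopulation larger than the dataset")


def _gene_names(config: ExprSimConfig) -> tuple[list[str], dict[str, list[str]]]:
    sets: dict[str, list[str]] = {}
    names: list[str] = []
    for prefix, key, n in [
        ("mt-Nd", "mito", config.n_mito),
        ("Rps", "ribo", config.n_ribo),
        ("Ndufa", "oxphos", config.n_oxphos),
        ("Fos", "ieg", config.n_ieg),
        ("Gm", "lnc", config.n_lnc),
    ]:
        sets[key] = [f"{prefix}{i}" for i in range(n)]
        names.extend(sets[key])
    marker_names = [m.gene for m in config.markers]
    names.extend(marker_names)
    n_bg = config.n_genes - len(names)
    names.extend(f"Bg{i}" for i in range(n_bg))
    return names, sets


def simulate_expression(config: ExprSimConfig) -> tuple[AnnData, dict]:
    """Simulate counts, labels and annotations with exact ground truth.

    Returns ``(adata, truth)``. ``adata.obs`` carries ``group`` and
    ``is_low_quality``; ``adata.var`` carries boolean gene-set columns.
    ``truth["pct_expressing"]`` reports the realized per-marker, per-group
    percent-expressing recomputed from the returned matrix;
    ``truth["low_quality_cells"]`` lists the planted low-quality cell ids.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_expr, rng_marker, rng_lq = [np.random.default_rng(c) for c in ss.spawn(3)]

    names, sets = _gene_names(config)
    n_genes = config.n_genes
    groups = list(config.group_sizes)
    labels = np.concatenate(
        [np.repeat(g, n) for g, n in config.group_sizes.items()]
    )
    n_cells = len(labels)

    gene_mean = config.base_mean * np.exp(
        rng_expr.normal(0, config.gene_log_sigma, n_genes)
    )
    lib = np.exp(rng_expr.normal(0, config.lib_log_sigma, n_cells))
    expressed = rng_expr.random((n_cells, n_genes)) < config.base_expr_rate
    lam = expressed * gene_mean[None, :] * lib[:, None]
    X = rng_expr.poisson(lam).astype(np.int64)
    # guarantee background-expressed entries are nonzero so the mito budget
    # below is well-defined; threshold statistics only care about positivity
    X[expressed & (X == 0)] = 1

    name_idx = {g: i for i, g in enumerate(names)}
    mito_idx = np.array([name_idx[g] for g in sets["mito"]])

    # scale mito genes so the baseline mito fraction is controlled
    non_mito = np.ones(n_genes, dtype=bool)
    non_mito[mito_idx] = False
    f0 = config.mito_base_fraction
    for c in range(n_cells):
        nm = X[c, non_mito].sum()
        target = f0 / (1.0 - f0) * nm
        cur = X[c, mito_idx].sum()
        if cur > 0 and target > 0:
            X[c, mito_idx] = rng_expr.multinomial(
                int(round(target)), X[c, mito_idx] / cur
            )
        elif target > 0:
            X[c, mito_idx] = rng_expr.multinomial(
                int(round(target)), np.ones(len(mito_idx)) / len(mito_idx)
            )

    # planted markers override the background column entirely
    truth_pct: list[dict] = []
    for m in config.markers:
        j = name_idx[m.gene]
        col = np.zeros(n_cells, dtype=np.int64)
        in_group = labels == m.group
        on = np.where(
            in_group,
            rng_marker.random(n_cells) < m.pct_in / 100.0,
            rng_marker.random(n_cells) < m.pct_out / 100.0,
        )
        col[on] = 1 + rng_marker.poisson(m.mean_expr - 1.0, size=int(on.sum()))
        X[:, j] = col

    # planted low-quality subpopulation
    lq = np.zeros(n_cells, dtype=bool)
    if config.low_quality is not None:
        spec = config.low_quality
        lq_idx = rng_lq.choice(n_cells, size=spec.n_cells, replace=False)
        lq[lq_idx] = True
        for c in lq_idx:
            keep = rng_lq.random(n_genes) < spec.gene_keep_prob
            keep[mito_idx] = True
            X[c, ~keep] = 0
            nm = X[c, non_mito].sum()
            if nm == 0:
                X[c, name_idx["Bg0"] if "Bg0" in name_idx else 0] = 1
                nm = 1
            target = int(round(spec.mito_fraction / (1.0 - spec.mito_fraction) * nm))
            X[c, mito_idx] = rng_lq.multinomial(
                max(target, 1), np.ones(len(mito_idx)) / len(mito_idx)
            )

    # no cell may end up empty (downstream metrics divide by the total)
    empty = X.sum(axis=1) == 0
    X[empty, 0] = 1

    obs = pd.DataFrame(
        {"group": pd.Categorical(labels), "is_low_quality": lq},
        index=[f"cell{i}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=pd.Index(names, name="gene"))
    for key in ("mito", "ribo", "oxphos", "ieg", "lnc"):
        var[key] = var.index.isin(sets[key])
    adata = AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)

    for m in config.markers:
        j = name_idx[m.gene]
        for g in groups:
            sel = labels == g
            truth_pct.append(
                {
                    "gene": m.gene,
                    "group": g,
                    "target_pct": m.pct_in if g == m.group else m.pct_out,
                    "realized_pct": 100.0 * float((X[sel, j] > 0).sum()) / int(sel.sum()),
                }
            )

    truth = {
        "pct_expressing": pd.DataFrame(truth_pct),
        "low_quality_cells": list(obs.index[lq]),
        "gene_sets": sets,
    }
    return adata, truth
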