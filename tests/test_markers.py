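"""Tests for single-cell QC and marker specificity scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse, stats

from duraquant import markers
from duraquant.synth import ExprSimConfig, LowQualitySpec, MarkerSpec, simulate_expression


def adata_from_counts(X, mito_genes=0):
    X = np.asarray(X)
    var = pd.DataFrame(index=[f"g{i}" for i in range(X.shape[1])])
    var["mito"] = [i < mito_genes for i in range(X.shape[1])]
    return AnnData(X=sparse.csr_matrix(X), var=var)


class TestHardFilter:
    def _adata(self, n_genes=800):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(6, n_genes)) + 1  # all genes detected
        return X

    def test_gene_count_boundary_strict(self):
        X = self._adata(800)
        X[0, 500:] = 0  # cell 0 detects exactly 500 genes
        ad = adata_from_counts(X, mito_genes=10)
        ad.X = sparse.csr_matrix(X)
        keep = markers.hard_filter_cells(ad)
        assert not keep[0] and keep[1]

    def test_mito_boundaries_strict(self):
        X = np.ones((3, 600), dtype=int)
        X[0, :60] = 0
        X[0, 60:] = 1          # 0% mito -> removed
        X[1, :60] = 10         # 600/1140 > 10% ... construct exactly 10%
        X[1] = 1
        X[1, 0] = 60           # mito 60+59=119? recompute below
        # build exact cases: total 600 genes, mito block = first 60
        X = np.ones((3, 600), dtype=int)
        X[0, :60] = 0                    # mito 0%
        X[1, :60] = 1                    # mito 60/600 = 10% exactly
        X[2, :60] = 0; X[2, 0] = 30      # mito 30/(30+540) ~ 5.3%
        ad = adata_from_counts(X, mito_genes=60)
        keep = markers.hard_filter_cells(ad)
        assert not keep[0]   # 0% strict lower bound
        assert not keep[1]   # 10% strict upper bound
        assert keep[2]

    def test_idempotent_and_all_pass(self):
        X = self._adata(800)
        ad = adata_from_counts(X, mito_genes=10)
        keep = markers.hard_filter_cells(ad)
        assert keep.all()
        keep2 = markers.hard_filter_cells(ad[keep].copy())
        assert keep2.all()

    def test_missing_mito_annotation_rejected(self):
        ad = adata_from_counts(np.ones((3, 10), dtype=int), mito_genes=0)
        with pytest.raises(ValueError, match="mitochondrial"):
            markers.hard_filter_cells(ad)


class TestQualityMetrics:
    def test_all_counts_mito_gives_100(self):
        X = np.zeros((2, 60), dtype=int)
        X[:, :5] = 3  # only mito genes expressed
        ad = adata_from_counts(X, mito_genes=5)
        sets = {"mito": [f"g{i}" for i in range(5)], "oxphos": ["g10"],
                "ribo": ["g11"], "ieg": ["g12"], "lnc": ["g13"]}
        m = markers.compute_quality_metrics(ad, sets)
        assert (m["pct_mito"] == 100.0).all()
        assert (m["pct_top50"] == 100.0).all()  # fewer than 50 genes expressed

    def test_matches_per_cell_brute_force(self, rng):
        X = rng.integers(0, 6, size=(5, 20))
        X[X.sum(axis=1) == 0, 0] = 1
        ad = adata_from_counts(X)
        sets = {
            "oxphos": ["g0", "g1"], "mito": ["g2", "g3"], "ribo": ["g4"],
            "ieg": ["g5", "g6"], "lnc": ["g7"],
        }
        m = markers.compute_quality_metrics(ad, sets)
        for c in range(5):
            total = X[c].sum()
            assert m["pct_mito"].iloc[c] == pytest.approx(100 * X[c, 2:4].sum() / total)
            assert m["pct_oxphos"].iloc[c] == pytest.approx(100 * X[c, :2].sum() / total)
            assert m["pct_ieg"].iloc[c] == pytest.approx(100 * X[c, 5:7].sum() / total)
            top = np.sort(X[c])[::-1][:50].sum()
            assert m["pct_top50"].iloc[c] == pytest.approx(100 * top / total)
            assert m["log2_genes"].iloc[c] == pytest.approx(np.log2((X[c] > 0).sum()))
            assert m["log2_umis"].iloc[c] == pytest.approx(np.log2(total))

    def test_zero_total_cell_rejected(self):
        X = np.zeros((2, 10), dtype=int)
        X[0, 0] = 1
        ad = adata_from_counts(X)
        sets = {k: ["g0"] for k in ("oxphos", "mito", "ribo", "ieg", "lnc")}
        with pytest.raises(ValueError, match="zero total"):
            markers.compute_quality_metrics(ad, sets)


class TestQualityNetwork:
    def _metrics(self, z_shift, n_normal=200, n_bad=40, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 1, size=(n_normal + n_bad, 8))
        base[n_normal:, 1] += z_shift  # shift the mito metric
        return pd.DataFrame(base, columns=markers.QC_METRICS)

    def test_homogeneous_metrics_never_flagged(self):
        m = pd.DataFrame(np.ones((50, 8)), columns=markers.QC_METRICS)
        flagged, _ = markers.flag_low_quality_clusters(m)
        assert not flagged.any()

    def test_infinite_threshold_flags_nothing(self):
        m = self._metrics(z_shift=6.0)
        flagged, _ = markers.flag_low_quality_clusters(
            m, markers.QualityGraphConfig(outlier_z=np.inf)
        )
        assert not flagged.any()

    def test_shifted_subpopulation_flagged(self):
        m = self._metrics(z_shift=6.0)
        flagged, clusters = markers.flag_low_quality_clusters(m)
        bad = np.zeros(len(m), dtype=bool)
        bad[200:] = True
        sens = (flagged & bad).sum() / bad.sum()
        spec = (~flagged & ~bad).sum() / (~bad).sum()
        assert sens >= 0.95 and spec >= 0.95
        assert clusters.loc[clusters["flagged"], "triggering_metrics"].str.contains(
            "pct_mito"
        ).any()

    def test_k_reduced_with_warning_for_tiny_datasets(self):
        m = self._metrics(z_shift=0, n_normal=8, n_bad=2)
        with pytest.warns(UserWarning, match="reduced k"):
            markers.flag_low_quality_clusters(m, markers.QualityGraphConfig(k=20))


class TestPercentExpressing:
    def test_forced_counts(self):
        X = np.zeros((10, 2), dtype=int)
        X[:7, 0] = 3
        X[:, 1] = 0
        X[:, 1][0] = 0
        ad = adata_from_counts(X)
        cells = np.ones(10, dtype=bool)
        assert markers.percent_expressing(ad, cells, "g0") == pytest.approx(70.0)
        assert markers.percent_expressing(ad, cells, "g1") == 0.0
        with pytest.raises(ValueError, match="empty"):
            markers.percent_expressing(ad, np.zeros(10, dtype=bool), "g0")

    def test_invariant_to_monotone_rescaling(self, rng):
        X = rng.integers(0, 4, size=(20, 5))
        ad1 = adata_from_counts(X)
        ad2 = adata_from_counts(X * 17)
        t = np.ones(20, dtype=bool)
        for g in ad1.var_names:
            assert markers.percent_expressing(ad1, t, g) == markers.percent_expressing(
                ad2, t, g
            )

    def test_planted_marker_within_binomial_error(self):
        cfg = ExprSimConfig(
            group_sizes={"FLC": 1000, "other": 200},
            markers=[MarkerSpec(gene="Mk", group="FLC", pct_in=70.0, pct_out=5.0)],
            seed=5,
        )
        ad, truth = simulate_expression(cfg)
        t = (ad.obs["group"] == "FLC").to_numpy()
        pct = markers.percent_expressing(ad, t, "Mk")
        sigma = 100 * np.sqrt(0.7 * 0.3 / 1000)
        assert abs(pct - 70.0) < 3 * sigma
        realized = truth["pct_expressing"].query("gene == 'Mk' and group == 'FLC'")
        assert pct == pytest.approx(realized["realized_pct"].iloc[0])


class TestWilcoxonDE:
    def _groups(self, X):
        n = X.shape[0] // 2
        t = np.zeros(X.shape[0], dtype=bool)
        t[:n] = True
        return t, ~t

    def test_identical_groups_zero_log2fc(self, rng):
        half = rng.integers(0, 5, size=(10, 6)) + 1
        X = np.vstack([half, half])
        ad = adata_from_counts(X)
        t, c = self._groups(X)
        de = markers.wilcoxon_de(ad, t, c)
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)

    def test_all_vs_none_statistic_extreme(self):
        X = np.ones((40, 3), dtype=int)
        X[:20, 0] = np.arange(2, 22)  # target cells express g0, comparator zero
        X[20:, 0] = 0
        X[:, 2] = 100 - X.sum(axis=1)  # equalize library sizes so g1 stays constant
        ad = adata_from_counts(X)
        t, c = self._groups(X)
        de = markers.wilcoxon_de(ad, t, c)
        assert de.loc["g0", "statistic"] == pytest.approx(400.0)  # n1*n2 extreme
        assert de.loc["g0", "pval"] < 1e-7
        # constant genes get p = 1 by convention
        assert de.loc["g1", "pval"] == 1.0

    def test_exact_p_matches_permutation_enumeration(self):
        # 4 vs 4, tie-free: enumerate all C(8,4) label splits for the exact
        # two-sided rank-sum tail, independent of the implementation
        vals = np.array([3.0, 5.0, 9.0, 11.0, 1.0, 2.0, 4.0, 6.0])
        lib = np.full(8, vals.sum())  # equal library sizes keep ranks intact
        X = np.column_stack([vals, lib - vals]).astype(int)
        ad = adata_from_counts(X)
        t = np.array([True] * 4 + [False] * 4)
        de = markers.wilcoxon_de(ad, t, ~t)
        ranks = stats.rankdata(vals)
        obs_u = ranks[:4].sum() - 4 * 5 / 2
        us = []
        for comb in itertools.combinations(range(8), 4):
            u = ranks[list(comb)].sum() - 4 * 5 / 2
            us.append(u)
        us = np.array(us)
        p_exact = np.mean(np.minimum(us, 16 - us) <= min(obs_u, 16 - obs_u))
        assert de.loc["g0", "pval"] == pytest.approx(p_exact, rel=1e-6)

    def test_null_pvalues_roughly_uniform(self, rng):
        X = rng.poisson(2.0, size=(60, 200)) + 1
        ad = adata_from_counts(X)
        t, c = self._groups(X)
        de = markers.wilcoxon_de(ad, t, c)
        ks = stats.kstest(de["pval"], "uniform")
        assert ks.pvalue > 0.01

    def test_bh_adjustment_monotone(self, rng):
        X = rng.poisson(2.0, size=(30, 50)) + 1
        X[:15, :5] += 6
        ad = adata_from_counts(X)
        t, c = self._groups(X)
        de = markers.wilcoxon_de(ad, t, c)
        assert (de["padj"] >= de["pval"] - 1e-15).all()
        s = de.sort_values("pval")
        assert s["padj"].is_monotonic_increasing

    def test_overlapping_groups_rejected(self):
        ad = adata_from_counts(np.ones((6, 3), dtype=int))
        t = np.array([True, True, True, False, False, False])
        with pytest.raises(ValueError, match="overlap"):
            markers.wilcoxon_de(ad, t, t)


class TestSpecificityRank:
    def _tables(self, rows):
        de = pd.DataFrame(rows).set_index("gene")[["statistic", "pval", "padj", "log2fc"]]
        pct = pd.DataFrame(rows).set_index("gene")[["pct_target", "pct_comparator"]]
        return de, pct

    def _row(self, gene, padj=0.01, log2fc=1.0, pct_t=80.0, pct_c=20.0):
        return dict(gene=gene, statistic=0.0, pval=padj, padj=padj, log2fc=log2fc,
                    pct_target=pct_t, pct_comparator=pct_c)

    def test_ratio_and_identity(self):
        de, pct = self._tables([self._row("A")])
        out = markers.specificity_rank(de, pct, n_comparator=100)
        assert out.loc["A", "specificity"] == pytest.approx(4.0)
        assert out.loc["A", "specificity"] * out.loc["A", "pct_comparator"] == pytest.approx(
            out.loc["A", "pct_target"]
        )

    def test_filter_boundaries(self):
        de, pct = self._tables([
            self._row("pct65", pct_t=65.0),          # fails 70% filter
            self._row("pct70", pct_t=70.0),          # boundary passes (>=)
            self._row("fc05", log2fc=0.5),           # fails 0.585 filter
            self._row("fc0585", log2fc=0.585),       # boundary passes
            self._row("p006", padj=0.06),            # fails padj
            self._row("p005", padj=0.05),            # boundary passes
        ])
        out = markers.specificity_rank(de, pct, n_comparator=100)
        assert not out.loc["pct65", "passes"] and out.loc["pct70", "passes"]
        assert not out.loc["fc05", "passes"] and out.loc["fc0585", "passes"]
        assert not out.loc["p006", "passes"] and out.loc["p005", "passes"]
        assert np.isnan(out.loc["pct65", "rank"])

    def test_zero_comparator_floored(self):
        de, pct = self._tables([self._row("Z", pct_c=0.0, pct_t=90.0)])
        out = markers.specificity_rank(de, pct, n_comparator=200)
        assert out.loc["Z", "floored"]
        assert out.loc["Z", "specificity"] == pytest.approx(90.0 / (100.0 / 200))

    def test_rank_order_and_tie_breaks(self):
        de, pct = self._tables([
            self._row("B", pct_t=80.0, pct_c=10.0),   # spec 8
            self._row("A", pct_t=80.0, pct_c=20.0),   # spec 4
            self._row("D", pct_t=90.0, pct_c=22.5),   # spec 4, higher pct_t
            self._row("C", pct_t=80.0, pct_c=20.0),   # spec 4, tie with A -> name
        ])
        out = markers.specificity_rank(de, pct, n_comparator=100)
        ranked = out[out["passes"]].sort_values("rank").index.tolist()
        assert ranked == ["B", "D", "A", "C"]

    def test_planted_marker_ranked_first(self):
        wins = 0
        for seed in range(20):
            cfg = ExprSimConfig(
                group_sizes={"FLC": 200, "other_nonimmune": 200},
                markers=[MarkerSpec(gene="Foxd1", group="FLC", pct_in=90, pct_out=2,
                                    mean_expr=6.0)],
                n_genes=120,
                seed=seed,
            )
            ad, _ = simulate_expression(cfg)
            t = (ad.obs["group"] == "FLC").to_numpy()
            c = ~t
            de = markers.wilcoxon_de(ad, t, c)
            pct = markers.percent_expressing_table(ad, t, c)
            out = markers.specificity_rank(de, pct, n_comparator=int(c.sum()))
            if out.loc["Foxd1", "rank"] == 1.0:
                wins += 1
        assert wins >= 19
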