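import numpy as np
import pandas as pd
import pytest

from methyldyn import (
    GeneModel,
    build_profile_matrix,
    gene_body_level,
    kmeans_profiles,
    length_vs_mch,
    mch_expression_correlation,
    metagene_profile,
    sample_correlation_cluster,
)

from conftest import make_methylome


def uniform_methylome(chrom_len, spacing, mc, cov, context="CAC", chrom="chr1"):
    rows = [(chrom, p, "+", context, mc, cov)
            for p in range(spacing, chrom_len, spacing)]
    return make_methylome(rows)


class TestGeneBodyLevel:
    def test_pooled_over_body_sites(self):
        m = make_methylome([("chr1", 100, "+", "CAC", 3, 10),
                            ("chr1", 200, "+", "CAT", 1, 10),
                            ("chr1", 900, "+", "CAC", 9, 10)])  # outside body
        gene = GeneModel("g", "chr1", "+", 50, 500)
        assert gene_body_level(m, gene, "CH") == pytest.approx(0.2)

    def test_zero_mc_gene(self):
        m = make_methylome([("chr1", 100, "+", "CAC", 0, 10)])
        assert gene_body_level(m, GeneModel("g", "chr1", "+", 50, 500), "CH") == 0.0

    def test_uncovered_gene_missing(self):
        m = make_methylome([("chr1", 100, "+", "CAC", 0, 0)])
        assert gene_body_level(m, GeneModel("g", "chr1", "+", 50, 500), "CH") is None


class TestMetageneProfile:
    def test_uniform_methylome_normalizes_to_one(self):
        m = uniform_methylome(300_000, 100, 2, 10)
        gene = GeneModel("g", "chr1", "+", 120_000, 180_000)
        prof = metagene_profile(m, gene, "CH", body_bins=10, flank_bp=50_000, flank_bins=5)
        np.testing.assert_allclose(prof.normalized, 1.0)

    def test_body_enriched_twofold(self):
        rows = []
        for p in range(100, 300_000, 100):
            inside = 120_000 <= p <= 180_000
            rows.append(("chr1", p, "+", "CAC", 4 if inside else 2, 10))
        m = make_methylome(rows)
        gene = GeneModel("g", "chr1", "+", 120_000, 180_000)
        prof = metagene_profile(m, gene, "CH", body_bins=10, flank_bp=50_000, flank_bins=5)
        body = prof.normalized[5:15]
        np.testing.assert_allclose(body, 2.0, rtol=1e-9)
        flanks = np.r_[prof.normalized[:5], prof.normalized[15:]]
        np.testing.assert_allclose(flanks, 1.0, rtol=1e-9)

    def test_minus_strand_profile_is_reverse_of_plus(self):
        rng = np.random.default_rng(7)
        rows = [("chr1", p, "+", "CAC", int(rng.integers(0, 9)), 10)
                for p in range(100, 300_000, 137)]
        m = make_methylome(rows)
        plus = metagene_profile(m, GeneModel("g", "chr1", "+", 120_000, 180_000),
                                "CH", body_bins=10, flank_bp=50_000, flank_bins=5)
        minus = metagene_profile(m, GeneModel("g", "chr1", "-", 180_000, 120_000),
                                 "CH", body_bins=10, flank_bp=50_000, flank_bins=5)
        np.testing.assert_allclose(minus.bins, plus.bins[::-1], equal_nan=True)

    def test_zero_flank_returns_raw_only(self):
        rows = [("chr1", p, "+", "CAC", 1, 10) for p in range(120_000, 180_000, 100)]
        m = make_methylome(rows)
        prof = metagene_profile(m, GeneModel("g", "chr1", "+", 120_000, 180_000),
                                "CH", body_bins=10, flank_bp=50_000, flank_bins=5)
        assert prof.normalized is None
        assert np.nansum(prof.bins) > 0

    def test_scale_invariance_of_normalization(self):
        # doubling every count leaves the normalized profile unchanged
        rng = np.random.default_rng(3)
        rows = [("chr1", p, "+", "CAC", int(rng.integers(1, 5)), 20)
                for p in range(100, 300_000, 113)]
        gene = GeneModel("g", "chr1", "+", 120_000, 180_000)
        kw = dict(body_bins=10, flank_bp=50_000, flank_bins=5)
        p1 = metagene_profile(make_methylome(rows), gene, "CH", **kw)
        doubled = [(c, p, s, ctx, 2 * mc, 2 * cov) for c, p, s, ctx, mc, cov in rows]
        p2 = metagene_profile(make_methylome(doubled), gene, "CH", **kw)
        np.testing.assert_allclose(p1.normalized, p2.normalized)


class TestKmeans:
    @staticmethod
    def planted_matrix(seed=0, n_per=60, noise=0.05):
        rng = np.random.default_rng(seed)
        a = np.sin(np.linspace(0, np.pi, 30)) + 1.0
        b = 2.0 - a
        rows = [a + rng.normal(0, noise, 30) for _ in range(n_per)]
        rows += [b + rng.normal(0, noise, 30) for _ in range(n_per)]
        idx = [f"g{i}" for i in range(2 * n_per)]
        return pd.DataFrame(rows, index=idx), np.r_[np.zeros(n_per), np.ones(n_per)]

    def test_two_archetype_recovery(self):
        mat, truth = self.planted_matrix()
        labels, _ = kmeans_profiles(mat, k=2, seed=0)
        agree = max((labels.to_numpy() == truth).mean(),
                    (labels.to_numpy() == 1 - truth).mean())
        assert agree >= 0.95

    def test_identical_rows_single_cluster(self):
        mat = pd.DataFrame(np.ones((10, 5)), index=[f"g{i}" for i in range(10)])
        labels, centroids = kmeans_profiles(mat, k=1, seed=0)
        assert labels.nunique() == 1
        np.testing.assert_allclose(centroids[0], 1.0)

    def test_seed_determinism(self):
        mat, _ = self.planted_matrix(seed=5)
        l1, c1 = kmeans_profiles(mat, k=4, seed=11)
        l2, c2 = kmeans_profiles(mat, k=4, seed=11)
        pd.testing.assert_series_equal(l1, l2)
        np.testing.assert_array_equal(c1, c2)

    def test_labels_ordered_by_cluster_size(self):
        mat, _ = self.planted_matrix()
        labels, _ = kmeans_profiles(mat, k=3, seed=0)
        sizes = labels.value_counts().sort_index().to_numpy()
        assert (np.diff(sizes) <= 0).all()

    def test_k_too_large_raises(self):
        mat = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            kmeans_profiles(mat, k=5, seed=0)


class TestSampleCorrelation:
    def test_duplicate_columns_correlate_perfectly(self, rng):
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.random(50)})
        corr, order, _ = sample_correlation_cluster(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_columns_negative(self, rng):
        x = rng.random(50)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.random(50)})
        corr, _, _ = sample_correlation_cluster(df)
        assert corr.loc["a", "b"] < 0

    def test_near_duplicates_merge_first(self, rng):
        x = rng.random(100)
        df = pd.DataFrame({"A": x, "B": x + rng.normal(0, 0.01, 100),
                           "C": rng.random(100)})
        _, order, linkage = sample_correlation_cluster(df)
        # first merge joins the two nearest leaves: A (0) and B (1)
        assert set(linkage[0, :2].astype(int)) == {0, 1}

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(60)
        df1 = pd.DataFrame({"a": x, "b": rng.random(60)})
        df2 = df1.copy()
        df2["a"] = np.exp(5 * df2["a"])  # monotone transform
        c1, _, _ = sample_correlation_cluster(df1)
        c2, _, _ = sample_correlation_cluster(df2)
        assert c1.loc["a", "b"] == pytest.approx(c2.loc["a", "b"])

    def test_sparse_sample_excluded(self, rng):
        df = pd.DataFrame({"a": rng.random(20), "b": rng.random(20),
                           "c": [np.nan] * 18 + [1.0, 2.0]})
        with pytest.warns(UserWarning, match="excluding"):
            corr, _, _ = sample_correlation_cluster(df)
        assert "c" not in corr.columns


class TestLengthTrend:
    @staticmethod
    def genes_with_levels(trend):
        genes = [GeneModel(f"g{i}", "chr1", "+", i * 100_000 + 1,
                           i * 100_000 + 10 ** (3 + i / 5)) for i in range(10)]
        lengths = np.array([g.length for g in genes], dtype=float)
        if trend == "up":
            vals = np.log10(lengths) / 10
        else:
            vals = np.full(10, 0.5)
        return genes, pd.Series(vals, index=[g.gene_id for g in genes])

    def test_planted_trend_monotone(self):
        genes, levels = self.genes_with_levels("up")
        out = length_vs_mch(genes, levels, n_bins=5)
        means = out["mean_level"].dropna().to_numpy()
        assert (np.diff(means) >= -1e-12).all()

    def test_flat_levels_flat_bins(self):
        genes, levels = self.genes_with_levels("flat")
        out = length_vs_mch(genes, levels, n_bins=5)
        np.testing.assert_allclose(out["mean_level"].dropna(), 0.5)

    def test_single_bin_is_global_mean(self):
        genes, levels = self.genes_with_levels("up")
        out = length_vs_mch(genes, levels, n_bins=1)
        assert out["mean_level"].iloc[0] == pytest.approx(levels.mean())


class TestMchExpressionCorrelation:
    def test_rank_reverse_gives_minus_one(self):
        mch = pd.Series(np.arange(20, dtype=float), index=[f"g{i}" for i in range(20)])
        expr = pd.Series(-np.arange(20, dtype=float) ** 2, index=mch.index)
        r, _ = mch_expression_correlation(mch, expr)
        assert r == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self, rng):
        idx = [f"g{i}" for i in range(1000)]
        r, _ = mch_expression_correlation(
            pd.Series(rng.random(1000), index=idx),
            pd.Series(rng.random(1000), index=idx))
        assert abs(r) < 0.1

    def test_constant_vector_undefined(self):
        idx = [f"g{i}" for i in range(20)]
        mch = pd.Series(np.arange(20, dtype=float), index=idx)
        expr = pd.Series(1.0, index=idx)
        assert mch_expression_correlation(mch, expr) == (None, None)

    def test_too_few_shared_genes_raises(self):
        a = pd.Series([1.0, 2.0], index=["g1", "g2"])
        with pytest.raises(ValueError):
            mch_expression_correlation(a, a)


class TestProfileMatrix:
    def test_short_genes_dropped_and_matrix_complete(self):
        m = uniform_methylome(400_000, 100, 2, 10)
        genes = [GeneModel("long", "chr1", "+", 150_000, 250_000),
                 GeneModel("short", "chr1", "+", 10_000, 10_020)]
        mat = build_profile_matrix(m, genes, "CH", body_bins=30,
                                   flank_bp=50_000, flank_bins=10)
        assert list(mat.index) == ["long"]
        assert not mat.isna().any().any()
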