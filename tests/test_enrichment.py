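import numpy as np
import pytest
import scipy.stats as st

from methyldyn import (
    RegionSet,
    extend_from_center,
    extend_sites,
    fisher_2x2,
    hypergeometric_enrichment,
    lowly_methylated_regions,
    mask_regions,
    overlap_flags,
    overlaps,
    ranksum,
    signal_profile,
)

from conftest import make_methylome


class TestOverlap:
    def test_one_base_overlap(self):
        assert overlaps(("chr1", 100, 200), ("chr1", 199, 300))

    def test_half_open_abutment_no_overlap(self):
        assert not overlaps(("chr1", 100, 200), ("chr1", 200, 300))

    def test_different_chromosomes(self):
        assert not overlaps(("chr1", 100, 200), ("chr2", 100, 200))

    def test_engine_matches_bruteforce_on_random_sets(self, rng):
        def random_set(n, name):
            ivs = []
            for _ in range(n):
                chrom = f"chr{rng.integers(1, 4)}"
                s = int(rng.integers(0, 10_000))
                ivs.append((chrom, s, s + int(rng.integers(1, 500))))
            return RegionSet(name, ivs)

        a, b = random_set(40, "a"), random_set(25, "b")
        # brute-force O(n*m) oracle over all 1,000 pairs
        brute = np.array([any(overlaps(x, y) for y in b.intervals)
                          for x in a.intervals])
        np.testing.assert_array_equal(overlap_flags(a, b), brute)


class TestExtension:
    def test_site_extension_gives_501bp_window(self):
        rs = extend_sites([("chr1", 1000)], pad=250)
        assert rs.intervals[0] == ("chr1", 749, 1250)
        assert rs.intervals[0][2] - rs.intervals[0][1] == 501

    def test_clipping_at_chromosome_bounds(self):
        rs = extend_sites([("chr1", 100)], pad=250, chrom_sizes={"chr1": 10_000})
        assert rs.intervals[0] == ("chr1", 0, 350)

    def test_zero_pad_single_base(self):
        rs = extend_sites([("chr1", 1000)], pad=0)
        assert rs.intervals[0] == ("chr1", 999, 1000)

    def test_center_extension(self):
        rs = extend_from_center(RegionSet("x", [("chr1", 100, 300)]), pad=250)
        assert rs.intervals[0] == ("chr1", 0, 450)


class TestLmrStandIn:
    @staticmethod
    def methylome_from_levels(levels, cov=10, start=100, step=50):
        rows = [("chr1", start + i * step, "+", "CGA", int(round(l * cov)), cov)
                for i, l in enumerate(levels)]
        return make_methylome(rows)

    def test_fully_methylated_no_regions(self):
        m = self.methylome_from_levels([0.9] * 20)
        assert len(lowly_methylated_regions(m)) == 0

    def test_low_run_becomes_one_region_with_exact_bounds(self):
        m = self.methylome_from_levels([0.9, 0.9] + [0.1] * 6 + [0.9, 0.9])
        rs = lowly_methylated_regions(m, max_level=0.5, min_cg=4)
        assert len(rs) == 1
        chrom, start, end = rs.intervals[0]
        assert (start, end) == (100 + 2 * 50 - 1, 100 + 7 * 50)  # first..last low site

    def test_run_shorter_than_min_cg_ignored(self):
        m = self.methylome_from_levels([0.9, 0.1, 0.1, 0.1, 0.9])
        assert len(lowly_methylated_regions(m, min_cg=4)) == 0

    def test_masking_removes_overlapping_peaks(self):
        peaks = RegionSet("p", [("chr1", 150, 250), ("chr1", 5000, 5100)])
        lmr = RegionSet("l", [("chr1", 200, 400)])
        kept = mask_regions(peaks, lmr)
        assert kept.intervals == [("chr1", 5000, 5100)]


class TestHypergeometricEnrichment:
    @staticmethod
    def region_grid(n, name, hit_first=0):
        ivs = [("chr1", i * 1000, i * 1000 + 500) for i in range(n)]
        hits = RegionSet("hits", [("chr1", i * 1000 + 10, i * 1000 + 20)
                                  for i in range(hit_first)])
        return RegionSet(name, ivs), hits

    def test_p_equals_direct_pmf_summation(self):
        fg, fg_hits = self.region_grid(20, "fg", hit_first=10)
        bg_ivs = [("chr2", i * 1000, i * 1000 + 500) for i in range(1000)]
        bg = RegionSet("bg", bg_ivs)
        hits = RegionSet("hits", fg_hits.intervals + [
            ("chr2", i * 1000 + 10, i * 1000 + 20) for i in range(100)])
        res = hypergeometric_enrichment(fg, bg, {"m": hits})[0]
        assert (res.k, res.n, res.K, res.N) == (10, 20, 100, 1000)
        # oracle: direct pmf summation of the upper tail
        oracle = sum(st.hypergeom.pmf(x, 1000, 100, 20) for x in range(10, 21))
        assert res.p == pytest.approx(oracle, rel=1e-10)
        assert res.direction == "enriched"

    def test_null_foreground_not_significant(self, rng):
        bg_ivs = [("chr1", i * 1000, i * 1000 + 500) for i in range(500)]
        bg = RegionSet("bg", bg_ivs)
        hit_idx = rng.choice(500, 100, replace=False)
        hits = RegionSet("hits", [("chr1", int(i) * 1000 + 10, int(i) * 1000 + 20)
                                  for i in hit_idx])
        fg_idx = rng.choice(500, 50, replace=False)
        fg = RegionSet("fg", [bg_ivs[i] for i in fg_idx])
        res = hypergeometric_enrichment(fg, bg, {"m": hits})[0]
        assert res.q >= 1e-5

    def test_maximal_enrichment_point_mass(self):
        bg_ivs = [("chr1", i * 1000, i * 1000 + 500) for i in range(100)]
        bg = RegionSet("bg", bg_ivs)
        hits = RegionSet("hits", [("chr1", i * 1000 + 10, i * 1000 + 20)
                                  for i in range(30)])
        fg = RegionSet("fg", bg_ivs[:30])  # exactly the hit-bearing regions
        res = hypergeometric_enrichment(fg, bg, {"m": hits})[0]
        assert res.p == pytest.approx(float(st.hypergeom.pmf(30, 100, 30, 30)), rel=1e-9)

    def test_depletion_direction(self):
        bg_ivs = [("chr1", i * 1000, i * 1000 + 500) for i in range(100)]
        bg = RegionSet("bg", bg_ivs)
        hits = RegionSet("hits", [("chr1", i * 1000 + 10, i * 1000 + 20)
                                  for i in range(80)])
        fg = RegionSet("fg", bg_ivs[80:])  # only hit-free regions
        res = hypergeometric_enrichment(fg, bg, {"m": hits})[0]
        assert res.direction == "depleted" and res.k == 0

    def test_empty_foreground_raises(self):
        bg = RegionSet("bg", [("chr1", 0, 10)])
        with pytest.raises(ValueError):
            hypergeometric_enrichment(
                RegionSet("fg", []), bg, {"m": RegionSet("h", [])})

    def test_order_invariance(self, rng):
        bg_ivs = [("chr1", i * 1000, i * 1000 + 500) for i in range(200)]
        hits = RegionSet("hits", [("chr1", i * 1000 + 10, i * 1000 + 20)
                                  for i in range(60)])
        fg_ivs = bg_ivs[:50]
        r1 = hypergeometric_enrichment(RegionSet("f", fg_ivs),
                                       RegionSet("b", bg_ivs), {"m": hits})[0]
        perm = [fg_ivs[i] for i in rng.permutation(50)]
        r2 = hypergeometric_enrichment(RegionSet("f", perm),
                                       RegionSet("b", bg_ivs[::-1]), {"m": hits})[0]
        assert r1.p == r2.p


class TestSignalProfile:
    def test_constant_track_flat_profile(self):
        track = RegionSet("t", [("chr1", 0, 100_000)], [2.5])
        out = signal_profile(track, [("chr1", 50_000)], halfwidth=1000, bin_bp=100)
        np.testing.assert_allclose(out["mean_signal"], 2.5)

    def test_central_enrichment_matches_loop_oracle(self):
        anchors = [("chr1", 10_000), ("chr1", 30_000)]
        track_iv, track_sc = [], []
        for _, pos in anchors:
            track_iv.append(("chr1", pos - 1 - 100, pos + 100))
            track_sc.append(4.0)
        track = RegionSet("t", track_iv, track_sc)
        out = signal_profile(track, anchors, halfwidth=1000, bin_bp=100)
        # brute-force per-base oracle
        n_bins = 20
        oracle = np.zeros(n_bins)
        for _, pos in anchors:
            center = pos - 1
            base = np.zeros(2000)
            for (c, s, e), sc in zip(track_iv, track_sc):
                lo, hi = max(s, center - 1000), min(e, center + 1000)
                if lo < hi:
                    base[lo - (center - 1000): hi - (center - 1000)] += sc
            oracle += base.reshape(n_bins, 100).mean(axis=1)
        np.testing.assert_allclose(out["mean_signal"], oracle / len(anchors))
        assert out["mean_signal"].iloc[9:11].min() > out["mean_signal"].iloc[0]

    def test_no_anchors_raises(self):
        track = RegionSet("t", [("chr1", 0, 100)], [1.0])
        with pytest.raises(ValueError):
            signal_profile(track, [])


class TestTwoSampleTests:
    def test_fisher_balanced_extreme_table(self):
        from scipy.special import comb
        _, p = fisher_2x2(10, 0, 0, 10)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_identical_groups_ranksum_p_near_one(self):
        x = np.arange(50, dtype=float)
        _, p = ranksum(x, x)
        assert p > 0.9

    def test_ranksum_null_pvalues_uniform(self, rng):
        # split one distribution into two groups 1,000 times; KS vs U(0,1)
        ps = []
        for _ in range(1000):
            pool = rng.normal(size=40)
            ps.append(ranksum(pool[:20], pool[20:])[1])
        ks = st.kstest(ps, "uniform")
        assert ks.pvalue > 0.001

    def test_fisher_null_type_one_error(self, rng):
        # binomial 2x2 tables under the null: rejection rate at alpha=0.05
        # within binomial CI of nominal (Fisher is conservative)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.binomial(30, 0.5)
            c = rng.binomial(30, 0.5)
            _, p = fisher_2x2(a, 30 - a, c, 30 - c)
            rej += p < 0.05
        assert rej / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
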