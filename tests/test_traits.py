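import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from recsel import (
    IntervalSet,
    TraitVariantSet,
    bonferroni_threshold,
    chi2_sum_test,
    enrich_traits,
    haplotype_r2,
    ld_proxy_expand,
    multiple_testing,
    rank_normalize,
)

from conftest import make_panel


class TestRankNormalize:
    def test_median_of_odd_count_maps_to_zero(self):
        z = rank_normalize(np.array([5.0, -3.0, 1.0, 10.0, 2.0]))
        assert z[np.argsort([5.0, -3.0, 1.0, 10.0, 2.0])[2]] == pytest.approx(0.0)

    def test_maximum_of_100_maps_to_expected_quantile(self):
        z = rank_normalize(np.arange(100, dtype=float))
        assert z.max() == pytest.approx(norm.ppf(0.995), abs=1e-9)
        assert z.max() == pytest.approx(2.576, abs=1e-3)

    def test_ties_get_identical_values(self):
        z = rank_normalize(np.array([1.0, 2.0, 2.0, 3.0]))
        assert z[1] == z[2]

    def test_order_preserving_and_centered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=501)
        z = rank_normalize(x)
        assert np.all(np.diff(z[np.argsort(x)]) >= 0)
        assert z.mean() == pytest.approx(0.0, abs=1e-6)
        assert z.std() == pytest.approx(1.0, abs=0.01)


class TestHaplotypeR2:
    def test_hand_computed_four_haplotypes(self):
        # haplotypes AB, Ab, aB, ab once each: D = 0.25 - 0.25 = 0 -> r2 = 0
        x = np.array([1, 1, 0, 0])
        y = np.array([1, 0, 1, 0])
        assert haplotype_r2(x, y) == 0.0
        # haplotypes AB x2, ab x2: D = 0.5 - 0.25 = 0.25, r2 = 1
        assert haplotype_r2(np.array([1, 1, 0, 0]), np.array([1, 1, 0, 0])) == 1.0
        # 3:1 coupling: p=q=0.5, f11=0.5 ... handmade intermediate case
        x = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        y = np.array([1, 1, 0, 1, 0, 0, 0, 1])
        p, q = x.mean(), y.mean()
        d = (x & y).mean() - p * q
        assert haplotype_r2(x, y) == pytest.approx(d * d / (p * (1 - p) * q * (1 - q)))

    def test_monomorphic_gives_zero(self):
        assert haplotype_r2(np.ones(4), np.array([1, 0, 1, 0])) == 0.0


class TestLdProxyExpand:
    def test_scored_variant_maps_to_itself(self):
        panel = make_panel(np.zeros((2, 4, 2), dtype=np.int8), positions=[100, 200])
        ts = TraitVariantSet("t", "disease", [("chr1", 100)])
        mapped, report = ld_proxy_expand(ts, panel, {"chr1:100", "chr1:200"})
        assert mapped == ["chr1:100"] and report.n_direct == 1

    def test_perfect_copy_proxy_chosen(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 2, (1, 20, 2))
        noise = rng.integers(0, 2, (1, 20, 2))
        haps = np.concatenate([col, noise, col]).astype(np.int8)
        panel = make_panel(haps, positions=[100, 150, 200])
        ts = TraitVariantSet("t", "disease", [("chr1", 100)])
        mapped, report = ld_proxy_expand(ts, panel, {"chr1:150", "chr1:200"})
        assert mapped == ["chr1:200"] and report.n_proxied == 1

    def test_weak_ld_dropped_and_duplicates_collapse(self):
        rng = np.random.default_rng(2)
        core = rng.integers(0, 2, (1, 50, 2))
        indep = rng.integers(0, 2, (1, 50, 2))
        haps = np.concatenate([core, core, indep]).astype(np.int8)
        panel = make_panel(haps, positions=[100, 110, 5000])
        scored = {"chr1:110"}
        ts = TraitVariantSet("t", "disease", [("chr1", 100), ("chr1", 5000), ("chr1", 110)])
        mapped, report = ld_proxy_expand(ts, panel, scored)
        # 100 proxies to 110, 110 maps to itself (collapse), 5000 dropped
        assert mapped == ["chr1:110"]
        assert report.n_dropped == 1


class TestChi2SumTest:
    def test_all_zero_scores(self):
        rec = chi2_sum_test(np.zeros(5))
        assert rec.statistic == 0.0 and rec.p == pytest.approx(1.0)

    def test_single_variant_quantile(self):
        rec = chi2_sum_test(np.array([1.96]))
        assert rec.statistic == pytest.approx(3.8416, abs=1e-3)
        assert rec.p == pytest.approx(0.05, abs=1e-3)

    def test_p_monotone_in_statistic(self):
        p_small = chi2_sum_test(np.array([0.0, 0.0])).p
        p_large = chi2_sum_test(np.array([3.0, 3.0])).p
        assert p_large < p_small

    def test_sign_indifference(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=12)
        assert chi2_sum_test(z).statistic == pytest.approx(
            chi2_sum_test(-z).statistic
        )

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            chi2_sum_test(np.array([]))


class TestMultipleTesting:
    def test_bonferroni_threshold_for_103_traits(self):
        thr = bonferroni_threshold(97 + 6)
        assert float(f"{thr:.2g}") == 0.00049

    def test_single_test_threshold(self):
        assert bonferroni_threshold(1) == 0.05

    def test_bh_step_up_hand_computation(self):
        q = multiple_testing(np.array([0.01, 0.02, 0.03, 0.04]), method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_flags(self):
        flags = multiple_testing(np.array([1e-5, 0.01]), n_tests=100)
        np.testing.assert_array_equal(flags, [True, False])


class TestEnrichTraits:
    def sds_table(self, n=400, seed=0, spike=None):
        rng = np.random.default_rng(seed)
        pos = np.arange(1, n + 1) * 1000
        z = rng.normal(size=n)
        if spike:
            z[spike] = 6.0
        return pd.DataFrame({"chrom": "chr1", "pos": pos, "final_z": z})

    def test_enriched_set_detected(self):
        spike = list(range(10))
        table = self.sds_table(spike=spike)
        sets = [
            TraitVariantSet("hot", "quantitative", [("chr1", (i + 1) * 1000) for i in spike]),
            TraitVariantSet("cold", "quantitative", [("chr1", i * 1000) for i in range(50, 60)]),
        ]
        res = enrich_traits(sets, table).set_index("trait")
        assert res.loc["hot", "p"] < 1e-6 < res.loc["cold", "p"]
        assert res.loc["hot", "inflation"] > 1 and res.loc["hot", "k"] == 10

    def test_trait_with_no_scored_variants_skipped_with_reason(self):
        table = self.sds_table()
        sets = [TraitVariantSet("ghost", "disease", [("chr9", 1)])]
        res = enrich_traits(sets, table)
        assert res.iloc[0]["skipped_reason"] == "no_mapped_variants"
        assert np.isnan(res.iloc[0]["p"])

    def test_locus_removal_drops_driving_signal(self):
        spike = list(range(10))
        table = self.sds_table(spike=spike)
        sets = [
            TraitVariantSet(
                "hot", "quantitative",
                [("chr1", (i + 1) * 1000) for i in spike]
                + [("chr1", i * 1000) for i in range(100, 110)],
            )
        ]
        excl = IntervalSet([("chr1", 0, 11_000)])
        before = enrich_traits(sets, table).iloc[0]
        after = enrich_traits(sets, table, exclude=excl).iloc[0]
        assert before["p"] < 1e-5
        assert after["k"] == 10
        assert after["p"] > 1e-2

    def test_no_overlap_statistic_stable_up_to_reranking(self):
        table = self.sds_table()
        ts = [TraitVariantSet("t", "disease", [("chr1", 200_000), ("chr1", 300_000)])]
        base = enrich_traits(ts, table).iloc[0]
        excl = IntervalSet([("chr1", 0, 1_500)])  # removes one unrelated variant
        after = enrich_traits(ts, table, exclude=excl).iloc[0]
        assert after["k"] == base["k"] == 2
        assert after["statistic"] == pytest.approx(base["statistic"], rel=0.1)

    def test_trait_fully_inside_excluded_loci_is_skipped(self):
        table = self.sds_table()
        ts = [TraitVariantSet("t", "disease", [("chr1", 1_000), ("chr1", 2_000)])]
        excl = IntervalSet([("chr1", 0, 3_000)])
        res = enrich_traits(ts, table, exclude=excl)
        assert res.iloc[0]["skipped_reason"] == "no_mapped_variants"
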