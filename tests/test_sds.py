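import numpy as np
import pandas as pd
import pytest

from recsel import (
    Arm,
    BinScheme,
    GapObservation,
    bin_standardize,
    fit_raw_sds,
    gap_lengths,
    meta_analyze,
)
from recsel.sds import REASON_CLASS_COUNT, _fit_many

from test_singletons import toy_catalog
from conftest import make_panel


def obs_from(n_der, gaps, variant_id="v"):
    n_der = np.asarray(n_der)
    gaps = np.asarray(gaps, dtype=float)
    return GapObservation(
        variant_id=variant_id,
        n_der=n_der,
        d_up=gaps / 2,
        d_down=gaps / 2,
        censored=np.zeros(len(n_der), dtype=bool),
    )


def gap_loglik(lam_a, lam_d, n_der, gaps):
    """Direct per-individual Gamma(2) log-likelihood (independent of the fit)."""
    lam = (2 - n_der) * lam_a + n_der * lam_d
    return float(np.sum(2 * np.log(lam) - lam * gaps))


class TestGapLengths:
    def test_flanking_distances(self):
        arm = Arm("chr1", 0, 20_000, "p")
        haps = np.zeros((1, 1, 2), dtype=np.int8)
        panel = make_panel(haps, positions=[4_000])
        catalog = toy_catalog([1_000, 9_000])  # carrier s0
        obs = gap_lengths(panel, catalog, 0, arm, "d1")
        assert obs.d_up[0] == 3_000 and obs.d_down[0] == 5_000
        assert obs.gap[0] == 8_000
        assert not obs.censored[0]

    def test_no_downstream_singleton_censors(self):
        arm = Arm("chr1", 0, 20_000, "p")
        panel = make_panel(np.zeros((1, 1, 2), dtype=np.int8), positions=[4_000])
        obs = gap_lengths(panel, toy_catalog([1_000]), 0, arm, "d1")
        assert obs.censored[0]

    def test_variant_outside_arm_is_an_error(self):
        arm = Arm("chr1", 0, 2_000, "p")
        panel = make_panel(np.zeros((1, 1, 2), dtype=np.int8), positions=[4_000])
        with pytest.raises(ValueError, match="outside arm"):
            gap_lengths(panel, toy_catalog([1_000]), 0, arm, "d1")

    def test_matches_linear_scan_oracle_on_random_data(self):
        rng = np.random.default_rng(5)
        arm = Arm("chr1", 0, 100_000, "p")
        n_samples = 8
        panel = make_panel(
            rng.integers(0, 2, (1, n_samples, 2)), positions=[50_000]
        )
        rows = []
        for i in range(n_samples):
            for p in np.unique(rng.integers(1, 100_001, size=30)):
                rows.append((f"s{i}", int(p)))
        df = pd.DataFrame(rows, columns=["carrier", "pos"])
        df["chrom"] = "chr1"
        df["vclass"] = "singleton"
        df["dataset"] = "d1"
        df["retained"] = True
        df["reason"] = "none"
        from recsel.singletons import CATALOG_COLUMNS, SingletonCatalog

        catalog = SingletonCatalog(df[CATALOG_COLUMNS])
        obs = gap_lengths(panel, catalog, 0, arm, "d1")
        for i in range(n_samples):
            mine = df[df["carrier"] == f"s{i}"]["pos"].to_numpy()
            before = mine[mine < 50_000]
            after = mine[mine > 50_000]
            if before.size == 0 or after.size == 0:
                assert obs.censored[i]
            else:
                assert obs.d_up[i] == 50_000 - before.max()
                assert obs.d_down[i] == after.min() - 50_000


class TestFitRawSds:
    def test_symmetric_homozygotes_give_zero(self):
        obs = obs_from([0] * 10 + [2] * 10, [4_000] * 20)
        fit = fit_raw_sds(obs)
        assert fit.reason is None
        assert fit.raw == pytest.approx(0.0, abs=1e-9)

    def test_doubled_derived_gap_gives_log_two(self):
        obs = obs_from([0] * 10 + [2] * 10, [1_000] * 10 + [2_000] * 10)
        fit = fit_raw_sds(obs)
        assert fit.raw == pytest.approx(np.log(2), abs=1e-9)
        # closed forms: lam_hat = 1 / mean(g) per homozygous class
        assert fit.lam_a == pytest.approx(1 / 1_000, rel=1e-9)
        assert fit.lam_d == pytest.approx(1 / 2_000, rel=1e-9)

    def test_homozygote_mle_equals_closed_form_to_1e9(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g0 = rng.gamma(2, 1 / (2 * 1e-4), size=15)
            g2 = rng.gamma(2, 1 / (2 * 3e-4), size=15)
            obs = obs_from([0] * 15 + [2] * 15, np.concatenate([g0, g2]))
            fit = fit_raw_sds(obs)
            assert fit.lam_a == pytest.approx(1 / g0.mean(), rel=1e-9)
            assert fit.lam_d == pytest.approx(1 / g2.mean(), rel=1e-9)

    def test_joint_mle_matches_grid_search(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n_der = rng.integers(0, 3, size=40)
            while (n_der <= 1).sum() < 10 or (n_der >= 1).sum() < 10:
                n_der = rng.integers(0, 3, size=40)
            la, ld = rng.uniform(5e-5, 5e-4, size=2)
            lam = (2 - n_der) * la + n_der * ld
            gaps = rng.gamma(2, 1 / lam)
            obs = obs_from(n_der, gaps)
            fit = fit_raw_sds(obs)
            assert fit.reason is None
            # two-stage grid over (log lam_a, log lam_d), final spacing 2e-5
            center = np.log([fit.lam_a, fit.lam_d])
            best = None
            for width, n in ((2.0, 81), (0.05, 51), (0.001, 101)):
                ga = np.exp(np.linspace(center[0] - width, center[0] + width, n))
                gd = np.exp(np.linspace(center[1] - width, center[1] + width, n))
                ll = np.array(
                    [[gap_loglik(a, d, n_der, gaps) for d in gd] for a in ga]
                )
                i, j = np.unravel_index(ll.argmax(), ll.shape)
                center = np.log([ga[i], gd[j]])
                best = (ga[i], gd[j])
            raw_grid = np.log(best[0]) - np.log(best[1])
            assert fit.raw == pytest.approx(raw_grid, abs=1e-3)

    def test_class_count_precondition(self):
        obs = obs_from([0] * 15 + [2] * 5, [1_000] * 20)
        assert fit_raw_sds(obs).reason == REASON_CLASS_COUNT

    def test_censored_individuals_are_dropped(self):
        obs = obs_from([0] * 10 + [2] * 10, [1_000] * 10 + [2_000] * 10)
        # append censored individuals with absurd gaps: must not move the fit
        obs2 = GapObservation(
            variant_id="v",
            n_der=np.concatenate([obs.n_der, [0, 2]]),
            d_up=np.concatenate([obs.d_up, [1e9, 1e9]]),
            d_down=np.concatenate([obs.d_down, [1e9, 1e9]]),
            censored=np.concatenate([obs.censored, [True, True]]),
        )
        assert fit_raw_sds(obs2).raw == pytest.approx(fit_raw_sds(obs).raw, abs=1e-12)

    def test_score_increases_as_derived_rate_shrinks(self):
        rng = np.random.default_rng(13)
        means = []
        for rho in (1.0, 0.5, 0.2):
            raws = []
            for _ in range(40):
                n_der = rng.integers(0, 3, size=60)
                lam = (2 - n_der) * 2e-4 + n_der * 2e-4 * rho
                obs = obs_from(n_der, rng.gamma(2, 1 / lam))
                fit = fit_raw_sds(obs)
                if fit.reason is None:
                    raws.append(fit.raw)
            means.append(np.mean(raws))
        assert means[0] < means[1] < means[2]


class TestBinStandardize:
    def test_two_scores_map_to_unit_z(self):
        z = bin_standardize(
            np.array([-1.0, 1.0]), np.array([0.5, 0.5]), BinScheme(min_occupancy=2)
        )
        np.testing.assert_allclose(np.sort(z), [-1.0, 1.0])

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(size=200)
        daf = rng.uniform(0.01, 0.99, size=200)
        z1 = bin_standardize(raw, daf)
        z2 = bin_standardize(raw + 7.5, daf)
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_group_moments_match_direct_recomputation(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(size=500)
        daf = rng.uniform(0.3, 0.32, size=500)  # lands in few bins
        scheme = BinScheme(min_occupancy=20)
        z = bin_standardize(raw, daf, scheme)
        bins = scheme.bin_of(daf)
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() >= scheme.min_occupancy:
                np.testing.assert_allclose(z[sel].mean(), 0.0, atol=1e-10)

    def test_bin_widths_follow_daf_regions(self):
        scheme = BinScheme()
        edges = scheme.edges
        widths = np.diff(edges)
        low = widths[edges[:-1] < 0.1 - 1e-9]
        mid = widths[(edges[:-1] >= 0.1 - 1e-9) & (edges[:-1] < 0.9 - 1e-9)]
        high = widths[edges[:-1] >= 0.9 - 1e-9]
        np.testing.assert_allclose(low, 0.005)
        np.testing.assert_allclose(mid, 0.01)
        np.testing.assert_allclose(high, 0.005)
        assert edges[0] == 0.0 and edges[-1] == 1.0

    def test_too_few_scores_is_an_error(self):
        with pytest.raises(ValueError):
            bin_standardize(np.array([1.0]), np.array([0.5]))


class TestMetaAnalyze:
    def make(self, z_rows, ns):
        rng = np.random.default_rng(0)
        filler = rng.normal(size=(300, len(ns)))
        zmat = np.vstack([np.asarray(z_rows, dtype=float), filler])
        df = pd.DataFrame(zmat, columns=[f"d{i}" for i in range(len(ns))])
        n = {f"d{i}": ns[i] for i in range(len(ns))}
        return meta_analyze(df, n)

    def test_equal_weights_equal_z(self):
        res = self.make([[1.0, 1.0, 1.0]], [100, 100, 100])
        assert res["meta_z"].iloc[0] == pytest.approx(np.sqrt(3))

    def test_two_datasets_closed_form(self):
        res = self.make([[2.0, 0.0]], [100, 100])
        assert res["meta_z"].iloc[0] == pytest.approx(np.sqrt(2))

    def test_missing_dataset_score_excludes_variant(self):
        res = self.make([[1.0, np.nan, 1.0]], [100, 100, 100])
        assert np.isnan(res["meta_z"].iloc[0])
        assert np.isnan(res["final_z"].iloc[0])

    def test_final_z_is_standardized_and_p_two_tailed(self):
        res = self.make([[1.0, 1.0]], [50, 200])
        fz = res["final_z"].to_numpy()
        ok = ~np.isnan(fz)
        assert np.nanmean(fz[ok]) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(fz[ok], ddof=1) == pytest.approx(1.0, rel=1e-12)
        from scipy.stats import norm

        np.testing.assert_allclose(
            res["p"], 2 * norm.sf(np.abs(fz)), rtol=1e-12
        )
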