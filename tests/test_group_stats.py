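"""Group inference: t maps, RM-ANOVA, ICC(3,1), cluster correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modparc import group_stats as gs
from modparc.core import StatMap


class TestOneSampleT:
    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(12)
        data = rng.standard_normal((98, 4000))
        out = gs.one_sample_t_map(list(data))
        crit = stats.t.ppf(0.975, 97)
        frac = (np.abs(out.stat) > crit).mean()
        assert abs(frac - 0.05) < 0.012  # 3 sigma Monte-Carlo band

    def test_identical_nonzero_input_capped_and_flagged(self):
        maps = [np.full((2, 2), 0.3)] * 5
        out = gs.one_sample_t_map(maps)
        assert np.all(out.stat == gs.T_CAP)
        assert out.flagged.all()

    def test_all_zero_voxel_reports_zero(self):
        maps = [np.zeros((2, 2))] * 5
        out = gs.one_sample_t_map(maps)
        assert np.all(out.stat == 0)

    def test_planted_effect_gives_large_t(self):
        rng = np.random.default_rng(3)
        effect = np.arctanh(0.3)
        data = effect + 0.1 * rng.standard_normal((30, 50))
        out = gs.one_sample_t_map(list(data))
        assert out.stat.mean() > 5

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            gs.one_sample_t_map([np.zeros(3)] * 2)


class TestSeedContrast:
    def _maps(self, rng, n=10, shape=(3, 3)):
        return {
            1: [rng.standard_normal(shape) for _ in range(n)],
            2: [rng.standard_normal(shape) for _ in range(n)],
        }

    def test_identical_seed_maps_give_zero(self, rng):
        maps = self._maps(rng)
        maps[2] = [m.copy() for m in maps[1]]
        out = gs.seed_contrast_map(maps, ("one_vs_rest", 1))
        assert np.allclose(out.stat, 0.0)

    def test_one_vs_rest_equals_pairwise_for_two_seeds(self, rng):
        maps = self._maps(rng)
        a = gs.seed_contrast_map(maps, ("one_vs_rest", 1))
        b = gs.seed_contrast_map(maps, ("pairwise", 1, 2))
        assert np.allclose(a.stat, b.stat)

    def test_subject_count_mismatch_rejected(self, rng):
        maps = self._maps(rng)
        maps[2] = maps[2][:-1]
        with pytest.raises(ValueError, match="mismatch"):
            gs.seed_contrast_map(maps, ("one_vs_rest", 1))


class TestRMAnova:
    def test_constant_cells_give_zero_f(self):
        data = np.full((6, 4, 3, 5), 2.5)
        out = gs.rm_anova_map(data)
        for sm in out.values():
            assert np.allclose(sm.stat, 0.0)

    def test_sums_of_squares_additive(self, rng):
        data = rng.standard_normal((8, 4, 3, 20))
        n, k, s = 8, 4, 3
        m = data.mean(axis=(0, 1, 2))
        ss_total = ((data - m) ** 2).sum(axis=(0, 1, 2))
        # recompute all components as the implementation defines them
        m_i = data.mean(axis=(1, 2)); m_j = data.mean(axis=(0, 2)); m_s = data.mean(axis=(0, 1))
        m_ij = data.mean(axis=2); m_is = data.mean(axis=1); m_js = data.mean(axis=0)
        parts = (
            k * s * ((m_i - m) ** 2).sum(axis=0)
            + n * s * ((m_j - m) ** 2).sum(axis=0)
            + n * k * ((m_s - m) ** 2).sum(axis=0)
            + s * ((m_ij - m_i[:, None] - m_j[None, :] + m) ** 2).sum(axis=(0, 1))
            + k * ((m_is - m_i[:, None] - m_s[None, :] + m) ** 2).sum(axis=(0, 1))
            + n * ((m_js - m_j[:, None] - m_s[None, :] + m) ** 2).sum(axis=(0, 1))
        )
        resid = ss_total - parts
        assert np.all(resid > -1e-8 * ss_total)
        assert np.allclose(parts + np.maximum(resid, 0), ss_total, rtol=1e-8)

    def test_seed_effect_only_design(self, rng):
        # seed-dependent, session-independent planted means
        n, k, s = 20, 4, 3
        seed_means = np.array([0.0, 0.5, 1.0])
        data = seed_means[None, None, :, None] + 0.2 * rng.standard_normal((n, k, s, 10))
        out = gs.rm_anova_map(data)
        assert np.median(out["seed"].stat) > 20
        assert np.median(out["session"].stat) < 4
        assert np.median(out["interaction"].stat) < 4

    def test_null_f_distribution_calibrated(self):
        rng = np.random.default_rng(77)
        n, k, s = 15, 2, 3
        data = rng.standard_normal((n, k, s, 3000))
        out = gs.rm_anova_map(data)
        df1, df2 = out["seed"].df
        ks = stats.kstest(out["seed"].stat, stats.f(df1, df2).cdf)
        assert ks.pvalue > 0.01

    def test_matches_statsmodels_anovarm_single_voxel(self, rng):
        from statsmodels.stats.anova import AnovaRM

        n, k, s = 7, 3, 4
        data = rng.standard_normal((n, k, s, 1))
        rows = [
            {"subject": i, "session": j, "seed": q, "y": data[i, j, q, 0]}
            for i in range(n)
            for j in range(k)
            for q in range(s)
        ]
        res = AnovaRM(
            pd.DataFrame(rows), "y", "subject", within=["session", "seed"]
        ).fit()
        out = gs.rm_anova_map(data)
        tab = res.anova_table
        assert out["session"].stat[0] == pytest.approx(tab.loc["session", "F Value"], rel=1e-8)
        assert out["seed"].stat[0] == pytest.approx(tab.loc["seed", "F Value"], rel=1e-8)
        assert out["interaction"].stat[0] == pytest.approx(
            tab.loc["session:seed", "F Value"], rel=1e-8
        )

    def test_missing_cells_rejected(self, rng):
        data = rng.standard_normal((5, 4, 3, 2))
        data[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            gs.rm_anova_map(data)


class TestICC:
    def test_constructed_table_bms10_ems2(self):
        # subject effects with SS = 10 and pure-interaction noise with
        # SS = 24 give BMS = 10, EMS = 2 -> ICC = (10-2)/(10+3*2) = 0.5
        a = np.array([2.0, -2.0, 1.0, -1.0, 0.0])
        u = np.array([1.0, -1.0, 0.0, 0.0, 0.0])
        v = np.array([1.0, -1.0, 0.0, 0.0])
        e = np.sqrt(6.0) * np.outer(u, v)
        data = a[:, None] + e  # (5 subjects, 4 sessions)
        n, k = data.shape
        bms = k * ((data.mean(axis=1) - data.mean()) ** 2).sum() / (n - 1)
        ss_total = ((data - data.mean()) ** 2).sum()
        ss_sess = n * ((data.mean(axis=0) - data.mean()) ** 2).sum()
        ems = (ss_total - bms * (n - 1) - ss_sess) / ((n - 1) * (k - 1))
        assert bms == pytest.approx(10.0)
        assert ems == pytest.approx(2.0)
        out = gs.icc31_map(data[:, :, None])
        assert out.stat[0] == pytest.approx(0.5, abs=1e-12)

    def test_identical_sessions_give_one(self, rng):
        subj = rng.standard_normal(8)
        data = np.repeat(subj[:, None], 4, axis=1)[:, :, None]
        out = gs.icc31_map(data)
        assert out.stat[0] == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(55)
        data = rng.standard_normal((100, 4, 500))
        out = gs.icc31_map(data)
        assert abs(out.stat.mean()) < 0.05

    def test_matches_pingouin_icc3(self, rng):
        import pingouin as pg

        data = rng.standard_normal((9, 4))
        df = pd.DataFrame(
            [
                {"subject": i, "rater": j, "y": data[i, j]}
                for i in range(9)
                for j in range(4)
            ]
        )
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="y")
        # consistency, single measures = ICC(3,1)
        expected = res.set_index("Type").loc["ICC(C,1)", "ICC"]
        out = gs.icc31_map(data[:, :, None])
        assert out.stat[0] == pytest.approx(expected, abs=1e-9)

    def test_shift_and_scale_invariance(self, rng):
        data = rng.standard_normal((10, 4, 20))
        base = gs.icc31_map(data).stat
        shifted = gs.icc31_map(data + 7.3).stat
        scaled = gs.icc31_map(data * 4.2).stat
        assert np.allclose(base, shifted, atol=1e-10)
        assert np.allclose(base, scaled, atol=1e-10)


class TestClusterNull:
    def test_unsmoothed_limit_small_min_size(self):
        mask = np.ones((30, 30, 20), bool)
        null = gs.mc_cluster_threshold(
            mask, 2.0, fwhm=0.0, voxel_p=0.001, n_iter=200, seed=5
        )
        assert null.min_cluster_size <= 3

    def test_min_size_monotone_in_fwhm(self):
        mask = np.ones((24, 24, 18), bool)
        sizes = [
            gs.mc_cluster_threshold(
                mask, 2.0, fwhm=f, voxel_p=0.001, n_iter=200, seed=6
            ).min_cluster_size
            for f in (0.0, 4.0, 10.0)
        ]
        assert sizes[0] <= sizes[1] <= sizes[2]
        assert sizes[2] > sizes[0]

    def test_alpha_one_disables_correction(self):
        mask = np.ones((10, 10, 10), bool)
        null = gs.mc_cluster_threshold(
            mask, 2.0, fwhm=4.0, voxel_p=0.01, alpha=1.0, n_iter=50, seed=7
        )
        assert null.min_cluster_size == 1


class TestExtractClusters:
    def _null(self, min_size):
        return gs.ClusterNull(10.0, 0.001, 1000, 0.05, min_size, 0)

    def test_empty_above_threshold(self):
        sm = StatMap(np.zeros((5, 5, 5)), "t", (10,))
        table = gs.extract_clusters(sm, 3.0, self._null(2))
        assert len(table) == 0

    def test_planted_blob_single_cluster(self):
        stat = np.zeros((20, 20, 10))
        stat[2:12, 2:12, 2:7] = 5.0  # 500-voxel blob
        sm = StatMap(stat, "t", (10,))
        table = gs.extract_clusters(sm, 3.0, self._null(300))
        assert len(table) == 1
        assert table.iloc[0]["size"] == 500
        assert table.iloc[0]["sign"] == 1

    def test_bridged_blobs_split_under_face_connectivity(self):
        stat = np.zeros((20, 9, 9))
        stat[2:6, 2:6, 2:6] = 5.0
        stat[10:14, 2:6, 2:6] = -5.0
        stat[6:10, 3, 3] = 1.0  # sub-threshold bridge
        sm = StatMap(stat, "t", (10,))
        table = gs.extract_clusters(sm, 3.0, self._null(10))
        assert len(table) == 2
        assert set(table["sign"]) == {1, -1}

    def test_small_clusters_discarded(self):
        stat = np.zeros((10, 10, 10))
        stat[1:3, 1, 1] = 9.0  # 2-voxel cluster
        sm = StatMap(stat, "t", (10,))
        assert len(gs.extract_clusters(sm, 3.0, self._null(5))) == 0
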