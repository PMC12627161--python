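"""Window detection, cluster permutation, jack-knife latencies, power."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rrsa
from rrsa.stats import paired_t_power


class TestOneSampleTSeries:
    def test_all_equal_to_mu_gives_t0_p1(self):
        data = np.full((5, 8), 0.02)
        t, p = rrsa.one_sample_t_series(data, 0.02)
        np.testing.assert_array_equal(t, 0.0)
        np.testing.assert_array_equal(p, 1.0)

    def test_matches_textbook_formula(self, rng):
        data = rng.normal(size=(7, 4))
        t, p = rrsa.one_sample_t_series(data, 0.1)
        from scipy import stats as sps

        mean, sd = data.mean(axis=0), data.std(axis=0, ddof=1)
        t_ref = (mean - 0.1) / (sd / np.sqrt(7))
        np.testing.assert_allclose(t, t_ref, atol=1e-12)
        np.testing.assert_allclose(p, 2 * sps.t.sf(np.abs(t_ref), 6), atol=1e-12)

    def test_strong_offset_tiny_p(self, rng):
        data = 0.02 + 0.5 + rng.normal(scale=1e-3, size=(31, 3))
        _, p = rrsa.one_sample_t_series(data, 0.02)
        assert (p < 1e-6).all()

    def test_zero_variance_off_mu_is_missing(self):
        data = np.full((4, 3), 1.0)
        t, p = rrsa.one_sample_t_series(data, 0.0)
        assert np.isnan(t).all() and np.isnan(p).all()

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            rrsa.one_sample_t_series(np.zeros((2, 5)), 0.0)


class TestChanceLevel:
    def test_median_of_three(self):
        assert rrsa.chance_level(np.array([[0.01, 0.02, 0.03]])) == 0.02

    def test_constant_series(self):
        assert rrsa.chance_level(np.full((4, 9), 0.07)) == pytest.approx(0.07)

    def test_matches_sort_based_oracle(self, rng):
        conds = rng.normal(size=(4, 31))
        avg = sorted(conds.mean(axis=0))
        assert rrsa.chance_level(conds) == pytest.approx(avg[15])


class TestBenjaminiYekutieli:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(rrsa.benjamini_yekutieli([0.03]), [0.03])

    def test_two_p_hand_stepup(self):
        # c(2) = 1.5: adjusted = (0.01*2*1.5/1, 0.04*2*1.5/2) -> (0.03, 0.06)
        np.testing.assert_allclose(
            rrsa.benjamini_yekutieli([0.01, 0.04]), [0.03, 0.06], atol=1e-12
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(rrsa.benjamini_yekutieli([1.0, 1.0, 1.0]), 1.0)

    @staticmethod
    def _stepup_oracle(p):
        """Hand step-up: sort, scale by m*c(m)/rank, monotonize from the top."""
        p = np.asarray(p, float)
        m = p.size
        c = np.sum(1.0 / np.arange(1, m + 1))
        order = np.argsort(p)
        scaled = p[order] * m * c / np.arange(1, m + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_oracle_and_dominates_bh(self, pvals):
        from statsmodels.stats.multitest import multipletests

        by = rrsa.benjamini_yekutieli(pvals)
        np.testing.assert_allclose(by, self._stepup_oracle(pvals), atol=1e-10)
        bh = multipletests(pvals, method="fdr_bh")[1]
        assert (by >= bh - 1e-12).all()
        assert (bh >= np.asarray(pvals) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rrsa.benjamini_yekutieli([0.5, 1.5])


class TestDetectWindows:
    def test_three_runs_and_envelope(self):
        times = np.arange(-800.0, 0.0)
        p = np.ones_like(times)
        for lo, hi in ((-730, -687), (-658, -579), (-560, -511)):
            p[(times >= lo) & (times <= hi)] = 0.01
        windows, envelope = rrsa.detect_windows(p, times, alpha=0.05)
        assert [(w.start_ms, w.end_ms) for w in windows] == [
            (-730.0, -687.0),
            (-658.0, -579.0),
            (-560.0, -511.0),
        ]
        assert (envelope.start_ms, envelope.end_ms) == (-730.0, -511.0)

    def test_nothing_significant(self):
        windows, envelope = rrsa.detect_windows(np.ones(10), np.arange(10.0))
        assert windows == [] and envelope is None

    def test_single_sample_window(self):
        p = np.ones(10)
        p[4] = 0.001
        windows, envelope = rrsa.detect_windows(p, np.arange(10.0))
        assert len(windows) == 1
        assert windows[0].start_ms == windows[0].end_ms == 4.0


class TestClusterPermutation:
    def test_identical_conditions_empty(self, rng):
        a = rng.normal(size=(10, 50))
        assert rrsa.cluster_permutation_test(a, a.copy(), 2.04, 1000, seed=1) == []

    def test_planted_effect_detected(self, rng):
        n, s = 20, 200
        a = rng.normal(size=(n, s))
        b = rng.normal(size=(n, s))
        window = slice(80, 130)
        a[:, window] += 5.0 * np.sqrt(2.0)  # 5 within-participant SDs of the diff
        clusters = rrsa.cluster_permutation_test(
            a, b, 2.04, 1000, seed=3, times=np.arange(s, dtype=float)
        )
        assert clusters
        top = clusters[0]
        covered = np.intersect1d(top.members, np.arange(80, 130)).size
        assert covered >= 0.9 * 50
        assert top.p_value < 0.01

    def test_sign_convention_invariance(self, rng):
        a = rng.normal(size=(12, 80))
        b = rng.normal(size=(12, 80))
        a[:, 30:45] += 1.0
        up = rrsa.cluster_permutation_test(a, b, 2.0, 500, seed=9, direction="greater")
        down = rrsa.cluster_permutation_test(b, a, 2.0, 500, seed=9, direction="less")
        assert [c.p_value for c in up] == [c.p_value for c in down]
        assert [c.mass for c in up] == [-c.mass for c in down]

    def test_relabeling_participants_changes_little(self, rng):
        a = rng.normal(size=(15, 60))
        b = rng.normal(size=(15, 60))
        a[:, 20:35] += 0.8
        p1 = rrsa.cluster_permutation_test(a, b, 2.0, 4000, seed=5)[0].p_value
        perm = rng.permutation(15)
        p2 = rrsa.cluster_permutation_test(a[perm], b[perm], 2.0, 4000, seed=5)[0].p_value
        assert abs(p1 - p2) < 0.02  # Monte-Carlo jitter only

    def test_seed_reproducibility(self, rng):
        a = rng.normal(size=(10, 40))
        b = rng.normal(size=(10, 40))
        a[:, 10:20] += 1.0
        r1 = rrsa.cluster_permutation_test(a, b, 2.0, 500, seed=42)
        r2 = rrsa.cluster_permutation_test(a, b, 2.0, 500, seed=42)
        assert [c.p_value for c in r1] == [c.p_value for c in r2]

    def test_guards(self, rng):
        a = rng.normal(size=(5, 10))
        with pytest.raises(ValueError, match="n_perm"):
            rrsa.cluster_permutation_test(a, a, 2.0, 50, seed=1)
        with pytest.raises(ValueError, match="seed"):
            rrsa.cluster_permutation_test(a, a, 2.0, 500)


class TestMaxTLatency:
    def test_monotone_rising_t(self):
        t = np.linspace(0, 5, 50)
        assert rrsa.max_t_latency(t, 2.04, np.arange(50.0)) == 49.0

    def test_single_sample_cluster(self):
        t = np.zeros(20)
        t[7] = 3.0
        assert rrsa.max_t_latency(t, 2.04, np.arange(20.0)) == 7.0

    def test_crafted_argmax_with_tie_toward_earlier(self):
        t = np.zeros(30)
        t[10:20] = 2.5
        t[12] = t[15] = 4.0  # tie: earlier sample wins
        assert rrsa.max_t_latency(t, 2.04, np.arange(30.0)) == 12.0

    def test_no_cluster_nan(self):
        assert np.isnan(rrsa.max_t_latency(np.zeros(10), 2.04))


class TestJackknifeLatency:
    def _bump(self, center, s=200, width=30, n=20, amp=6.0, rng=None):
        x = np.arange(s)
        env = amp * np.exp(-0.5 * ((x - center) / (width / 4)) ** 2)
        data = np.tile(env, (n, 1))
        if rng is not None:
            data = data + rng.normal(scale=0.5, size=data.shape)
        return data

    def test_deterministic_shift_recovered_exactly(self):
        base = np.zeros((20, 200))
        a = self._bump(80)
        b = self._bump(100)  # shifted by exactly 20 samples
        res = rrsa.jackknife_latency_comparison(
            a, b, base, 2.04, 1000, seed=2, times=np.arange(200.0)
        )
        # every leave-one-out subsample sees the same shift, so the latency
        # difference is exact; absolute latencies are degenerate here because
        # a zero-variance effect has no well-defined per-sample t ordering
        assert res.delta_ms == -20.0
        assert np.all(res.latencies_a - res.latencies_b == -20.0)
        assert res.p_value < 0.05
        assert res.n_unstable == 0

    def test_identical_conditions_null(self):
        base = np.zeros((12, 150))
        a = self._bump(60, s=150, n=12)
        res = rrsa.jackknife_latency_comparison(
            a, a.copy(), base, 2.04, 1000, seed=4, times=np.arange(150.0)
        )
        assert res.delta_ms == 0.0
        assert res.p_value > 0.9

    def test_noisy_shift_recovered_with_correction_reported(self, rng):
        base = np.zeros((24, 200))
        a = self._bump(90, rng=rng, n=24)
        b = self._bump(120, rng=rng, n=24)
        res = rrsa.jackknife_latency_comparison(
            a, b, base, 2.04, 1000, seed=6, times=np.arange(200.0)
        )
        assert res.delta_ms == pytest.approx(-30.0, abs=5.0)
        assert res.p_value < 0.01
        # the corrected statistic is the naive one shrunk by (n - 1)
        assert res.t_corrected == pytest.approx(res.t_uncorrected / 23)


class TestCTSClusterTest:
    def test_all_zero_matrices_empty(self):
        mats = np.zeros((8, 10, 10))
        assert rrsa.cts_cluster_test(mats, 0.0, 2.04, 500, seed=1) == []

    def test_planted_diagonal_block(self, rng):
        n, s = 12, 30
        mats = rng.normal(scale=0.1, size=(n, s, s))
        for k in range(8, 16):  # near-diagonal block effect
            mats[:, k, max(0, k - 2) : k + 3] += 0.5
        clusters = rrsa.cts_cluster_test(
            mats, 0.0, 2.04, 1000, seed=7, n_tests=4, times=np.arange(s, dtype=float)
        )
        assert clusters
        top = clusters[0]
        assert top.p_value < 0.05
        rows = np.unique(top.members[:, 0])
        assert set(range(8, 16)) <= set(rows.tolist())

    def test_bonferroni_scaling(self, rng):
        mats = rng.normal(scale=0.1, size=(10, 20, 20))
        mats[:, 5:9, 5:9] += 0.4
        one = rrsa.cts_cluster_test(mats, 0.0, 2.04, 500, seed=8, n_tests=1)
        four = rrsa.cts_cluster_test(mats, 0.0, 2.04, 500, seed=8, n_tests=4)
        assert four[0].p_value == pytest.approx(min(1.0, 4 * one[0].p_value))
        assert four[0].p_raw == one[0].p_raw

    def test_null_calibration_off_diagonal(self, rng):
        # noise-only matrices: significant clusters in <= 5% of replicates
        hits = 0
        for _ in range(100):
            mats = rng.normal(size=(8, 12, 12))
            clusters = rrsa.cts_cluster_test(mats, 0.0, 2.04, 200, seed=rng, n_tests=1)
            hits += any(c.p_value <= 0.05 for c in clusters)
        assert hits <= 10  # 95% binomial envelope around 0.05


class TestPower:
    def test_monotone_in_n(self):
        powers = [paired_t_power(n, 0.5) for n in (5, 10, 20, 40)]
        assert powers == sorted(powers)

    def test_minimal_n_is_first_to_reach_power(self):
        n = rrsa.minimal_sample_size_paired_t(0.73, 0.05, 0.80)
        assert paired_t_power(n, 0.73) >= 0.80
        assert paired_t_power(n - 1, 0.73) < 0.80

    def test_matches_statsmodels_solver(self):
        from statsmodels.stats.power import TTestPower

        n_ref = TTestPower().solve_power(effect_size=0.73, alpha=0.05, power=0.80)
        assert rrsa.minimal_sample_size_paired_t(0.73, 0.05, 0.80) == int(np.ceil(n_ref))
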