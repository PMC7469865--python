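"""Brain-behavior correlations, meta-analytic combination, cluster permutation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erpdecode.errors import DataError
from erpdecode.linkage import (behavior_summaries, cluster_permutation,
                               corr_timecourse, liptak_stouffer,
                               univariate_corr)

TIMES = np.arange(0.0, 1200.0 + 1, 20.0)  # 61 points


class TestCorrTimecourse:
    def test_behavior_copy_of_accuracy_column(self, rng):
        acc = rng.normal(0.7, 0.1, size=(10, len(TIMES)))
        ct = corr_timecourse(acc, acc[:, 17].copy(), TIMES)
        assert ct.r[17] == pytest.approx(1.0)
        assert ct.p[17] < 1e-9

    def test_matches_pearson_oracle_five_subjects(self):
        acc = np.array([[0.52, 0.61], [0.55, 0.72], [0.49, 0.58],
                        [0.62, 0.80], [0.58, 0.66]])
        beh = np.array([-1.2, -0.4, -1.9, 0.3, -0.8])
        ct = corr_timecourse(acc, beh, np.array([0.0, 20.0]))
        for t in range(2):
            r_ref, p_ref = stats.pearsonr(acc[:, t], beh)
            assert ct.r[t] == pytest.approx(r_ref)
            assert ct.p[t] == pytest.approx(p_ref)

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            acc = rng.normal(size=(12, 3))
            beh = rng.normal(size=12)
            ps.extend(corr_timecourse(acc, beh, np.arange(3) * 20.0).p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_zero_variance_flagged(self, rng):
        acc = rng.normal(size=(8, 4))
        acc[:, 2] = 0.5
        with pytest.warns(RuntimeWarning):
            ct = corr_timecourse(acc, rng.normal(size=8), np.arange(4) * 20.0)
        assert np.isnan(ct.r[2])

    def test_window_restriction(self, rng):
        acc = rng.normal(size=(8, len(TIMES)))
        ct = corr_timecourse(acc, rng.normal(size=8), TIMES, window=(0.0, 560.0))
        assert ct.times[0] == 0.0 and ct.times[-1] == 560.0

    def test_too_few_subjects(self, rng):
        with pytest.raises(DataError):
            corr_timecourse(rng.normal(size=(3, 5)), rng.normal(size=3),
                            np.arange(5) * 20.0)


class TestLiptakStouffer:
    def test_p_half_combines_to_half(self):
        res = liptak_stouffer([np.array([0.5]), np.array([0.5])], [30, 26])
        assert res.p_combined[0] == pytest.approx(0.5)
        assert np.allclose(res.z_per_dataset, 0.0)

    def test_single_dataset_identity(self, rng):
        p = rng.uniform(0.01, 0.99, 20)
        res = liptak_stouffer([p], [30])
        assert np.allclose(res.p_combined, p)
        assert np.allclose(res.z_combined, res.z_per_dataset[0])

    def test_frozen_normal_cdf_oracle(self):
        # p1 = p2 = 0.05, N = (30, 26): Z and p computed independently from
        # the standard-normal CDF before the implementation existed
        res = liptak_stouffer([np.array([0.05]), np.array([0.05])], [30, 26])
        assert res.z_combined[0] == pytest.approx(2.324688406142883, abs=1e-9)
        assert res.p_combined[0] == pytest.approx(0.010044313835816587, abs=1e-9)

    def test_order_invariance_equal_information(self, rng):
        p1, p2 = rng.uniform(0.01, 0.99, 10), rng.uniform(0.01, 0.99, 10)
        a = liptak_stouffer([p1, p2], [30, 26])
        b = liptak_stouffer([p2, p1], [26, 30])
        assert np.allclose(a.p_combined, b.p_combined)

    def test_extreme_p_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            res = liptak_stouffer([np.array([0.0]), np.array([1.0])], [30, 26])
        assert np.isfinite(res.z_combined).all()


def _coupled_cohort(rng, n_sub, n_t, window_idx, strength=1.0):
    """Accuracy series with a subject-specific bump confined to a window,
    and behavior negatively coupled to the bump size."""
    acc = 0.7 + rng.normal(0, 0.05, size=(n_sub, n_t))
    bump = rng.normal(0, 0.08, size=n_sub)
    acc[:, window_idx] += bump[:, None]
    beh = -strength * bump + rng.normal(0, 0.02, size=n_sub)
    return acc, beh


class TestClusterPermutation:
    def test_observed_clusters_match_direct_recomputation(self, rng):
        acc1, beh1 = _coupled_cohort(rng, 30, 61, slice(23, 34))
        acc2, beh2 = _coupled_cohort(rng, 26, 61, slice(23, 34))
        res = cluster_permutation([acc1, acc2], [beh1, beh2], TIMES,
                                  n_perm=200, seed=0)
        ct1 = corr_timecourse(acc1, beh1, TIMES)
        ct2 = corr_timecourse(acc2, beh2, TIMES)
        meta = liptak_stouffer([ct1.p, ct2.p], [30, 26])
        assert np.allclose(res.p_pointwise, meta.p_combined)
        sig = meta.p_combined < 0.05
        total = sum(c.size for c in res.clusters)
        assert total == sig.sum()

    def test_planted_window_recovered_significant_negative(self, rng):
        acc1, beh1 = _coupled_cohort(rng, 30, 61, slice(23, 34))
        acc2, beh2 = _coupled_cohort(rng, 26, 61, slice(23, 34))
        res = cluster_permutation([acc1, acc2], [beh1, beh2], TIMES,
                                  n_perm=500, seed=1)
        sig = [c for c in res.clusters if c.significant]
        assert sig
        best = max(sig, key=lambda c: c.size)
        # overlaps the planted 460-660 ms window with negative correlation
        assert best.start_ms < 660 and best.end_ms > 460
        sel = (res.times >= best.start_ms) & (res.times < best.end_ms)
        assert res.r_observed[0][sel].mean() < 0

    def test_shared_shuffle_preserved_across_time(self, rng):
        # accuracy constant over time per subject: every permutation gives
        # the same p at all points, so null runs are all-or-nothing
        acc = np.tile(rng.normal(size=(12, 1)), (1, 20))
        beh = rng.normal(size=12)
        res = cluster_permutation([acc], [beh], np.arange(20) * 20.0,
                                  n_perm=300, seed=2)
        assert set(np.unique(res.null_sizes)) <= {0, 20}

    def test_extreme_cluster_significant_with_consistent_label(self, rng):
        n_sub, n_t = 26, 80
        acc = rng.normal(0, 0.05, size=(n_sub, n_t))
        bump = rng.normal(0, 0.2, size=n_sub)
        acc[:, 20:60] += bump[:, None]  # coupling confined to 40 points
        beh = -bump + rng.normal(0, 0.01, size=n_sub)
        res = cluster_permutation([acc], [beh], np.arange(n_t) * 20.0,
                                  n_perm=500, seed=3)
        big = max(res.clusters, key=lambda c: c.size)
        assert big.size >= 35 and big.p < 0.05
        # the "<.001" label appears exactly when no null value reaches the size
        for c in res.clusters:
            assert (c.p_label == "<.001") == (c.p == 0.0)

    def test_mismatched_time_axes_rejected(self, rng):
        with pytest.raises(DataError):
            cluster_permutation([rng.normal(size=(10, 20)),
                                 rng.normal(size=(10, 21))],
                                [rng.normal(size=10), rng.normal(size=10)],
                                np.arange(20) * 20.0, n_perm=100)


class TestUnivariateCorr:
    def test_single_channel_reduces_to_corr_timecourse(self, rng):
        waves = rng.normal(size=(12, 1, 25))
        beh = rng.normal(size=12)
        times = np.arange(25) * 20.0
        res = univariate_corr(waves, beh, times, n_perm=150, seed=4)
        ct = corr_timecourse(waves[:, 0, :], beh, times)
        assert np.allclose(res["r"][0], ct.r)
        assert np.allclose(res["p_fdr"][0], ct.p)  # BH over one channel = identity

    def test_planted_channel_time_attains_min_p(self, rng):
        waves = rng.normal(size=(14, 5, 25))
        beh = waves[:, 3, 11].copy()
        res = univariate_corr(waves, beh, np.arange(25) * 20.0, n_perm=100, seed=5)
        ch, t = np.unravel_index(np.argmin(res["p_fdr"]), res["p_fdr"].shape)
        assert (ch, t) == (3, 11)

    def test_null_rarely_significant(self, rng):
        waves = rng.normal(size=(12, 4, 30))
        beh = rng.normal(size=12)
        res = univariate_corr(waves, beh, np.arange(30) * 20.0, n_perm=300, seed=6)
        sig = [c for cl in res["clusters"] for c in cl if c.p < 0.05]
        assert len(sig) == 0


class TestBehaviorSummaries:
    def test_hand_values(self):
        t = pd.DataFrame({"rt": [400.0, 500.0, 600.0], "correct": [True] * 3})
        out = behavior_summaries(t)
        assert out["mean_rt"] == 500.0 and out["median_rt"] == 500.0

    def test_validity_difference(self):
        t = pd.DataFrame({
            "rt": [500.0, 500.0, 560.0, 560.0],
            "correct": [True] * 4,
            "validity": ["valid", "valid", "invalid", "invalid"]})
        out = behavior_summaries(t)
        assert out["rt_difference"] == pytest.approx(60.0)

    def test_matches_brute_force_random_tables(self, rng):
        rt = rng.normal(500, 60, 50)
        correct = rng.random(50) > 0.1
        val = rng.choice(["valid", "invalid"], 50)
        t = pd.DataFrame({"rt": rt, "correct": correct, "validity": val})
        out = behavior_summaries(t)
        keep = correct
        assert out["mean_rt"] == pytest.approx(rt[keep].mean())
        assert out["median_rt"] == pytest.approx(np.median(rt[keep]))
        want = rt[keep & (val == "invalid")].mean() - rt[keep & (val == "valid")].mean()
        assert out["rt_difference"] == pytest.approx(want)

    def test_no_correct_trials_raises(self):
        t = pd.DataFrame({"rt": [500.0], "correct": [False]})
        with pytest.raises(DataError):
            behavior_summaries(t)
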