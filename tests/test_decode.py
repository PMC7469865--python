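"""Trial-averaged decoding: partitioning, normalization, SVM folds, smoothing."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import chisquare

from erpdecode.decode import (DecoderConfig, build_patterns,
                              channel_subset_decode, crossval_accuracy_at_time,
                              decode_timecourse, partition_trials,
                              smooth_timecourse, z_normalize)
from erpdecode.errors import ChannelError, ConfigurationError, DataError
from conftest import make_epochs


class TestPartition:
    def test_divisible_no_omission(self, rng):
        cond = np.array(["a"] * 9 + ["b"] * 9, dtype=object)
        a = partition_trials(cond, 3, rng)
        assert (a >= 0).all()
        for c in "ab":
            counts = np.bincount(a[cond == c], minlength=3)
            assert counts.tolist() == [3, 3, 3]

    def test_remainder_omitted(self, rng):
        cond = np.array(["a"] * 10, dtype=object)
        a = partition_trials(cond, 3, rng)
        assert (a == -1).sum() == 1
        assert np.bincount(a[a >= 0]).tolist() == [3, 3, 3]

    def test_uniform_assignment_chi_square(self):
        # each of 6 trials should land in each of 3 groups equally often
        counts = np.zeros((6, 3))
        cond = np.array(["a"] * 6, dtype=object)
        for seed in range(3000):
            a = partition_trials(cond, 3, np.random.default_rng(seed))
            for t in range(6):
                counts[t, a[t]] += 1
        for t in range(6):
            assert chisquare(counts[t]).pvalue > 1e-4

    def test_too_few_trials(self, rng):
        with pytest.raises(DataError):
            partition_trials(np.array(["a", "a"], dtype=object), 3, rng)


class TestZNormalize:
    def test_hand_computed_sample_sd(self):
        assert np.allclose(z_normalize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_constant_vector_maps_to_zeros_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = z_normalize([4.0, 4.0, 4.0])
        assert np.array_equal(out, np.zeros(3))

    def test_shift_invariance(self, rng):
        v = rng.normal(size=8)
        assert np.allclose(z_normalize(v), z_normalize(v + 123.4))


def oracle_linear_svm(x_train, y_train, x_test, C=1.0):
    """Independent linear-SVM oracle: primal hinge-loss minimization.

    Minimizes 0.5*||w||^2 + C*sum(hinge) by numerical optimization (BFGS on
    a smoothed hinge refined by Nelder-Mead verification is overkill here;
    SLSQP on the exact objective suffices for these tiny separable
    instances).  Returns predicted labels in {0, 1}.
    """
    y = np.where(np.asarray(y_train) == 1, 1.0, -1.0)
    n, d = x_train.shape

    def objective(params):
        w, b = params[:d], params[d]
        margins = y * (x_train @ w + b)
        return 0.5 * w @ w + C * np.maximum(0.0, 1.0 - margins).sum()

    best = None
    for trial in range(5):
        x0 = np.random.default_rng(trial).normal(0, 0.1, d + 1)
        res = minimize(objective, x0, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    w, b = best.x[:d], best.x[d]
    return (x_test @ w + b > 0).astype(int)


class TestCrossval:
    def _patterns(self, rng, sep=5.0, noise=0.0):
        base = rng.normal(size=(2, 3, 4))
        base[0] -= sep / 2
        base[1] += sep / 2
        return base + rng.normal(0, noise, size=base.shape)

    def test_separable_patterns_perfect(self, rng):
        pat = self._patterns(rng, sep=6.0, noise=0.1)
        assert crossval_accuracy_at_time(pat) == 1.0

    def test_shuffled_labels_long_run_chance(self, rng):
        accs = []
        for _ in range(300):
            pat = rng.normal(size=(2, 3, 4))  # label carries no information
            accs.append(crossval_accuracy_at_time(pat))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_matches_margin_classifier_oracle(self):
        # fixed small instance: 3 groups x 2 conditions x 4 channels
        rng = np.random.default_rng(7)
        for _ in range(10):
            pat = rng.normal(size=(2, 3, 4)) + np.array([-0.8, 0.8])[:, None, None]
            correct = 0
            for held in range(3):
                tr = [g for g in range(3) if g != held]
                x_train = pat[:, tr].reshape(-1, 4)
                y_train = np.repeat([0, 1], 2)
                pred = oracle_linear_svm(x_train, y_train, pat[:, held])
                correct += int((pred == np.array([0, 1])).sum())
            assert crossval_accuracy_at_time(pat) == pytest.approx(correct / 6)

    def test_degenerate_identical_patterns_deterministic(self):
        pat = np.zeros((2, 3, 4))
        acc = crossval_accuracy_at_time(pat)
        # boundary ties resolve to the first class: one of two test patterns
        # per fold is "correct"
        assert acc == 0.5


class TestBuildPatterns:
    def test_group_means_then_z(self, rng):
        data = rng.normal(size=(12, 3, 5))
        cond = np.array(["a"] * 6 + ["b"] * 6, dtype=object)
        ep = make_epochs(data, condition=cond)
        assignment = partition_trials(cond, 3, rng)
        pat = build_patterns(ep, assignment, time_index=2)
        assert pat.shape == (2, 3, 3)
        sel = (cond == "a") & (assignment == 0)
        want = z_normalize(data[sel, :, 2].mean(axis=0))
        assert np.allclose(pat[0, 0], want)
        # per-pattern normalization: mean 0, sample SD 1
        assert np.allclose(pat.mean(axis=-1), 0.0, atol=1e-12)
        assert np.allclose(pat.std(axis=-1, ddof=1), 1.0)


class TestSmoothing:
    def test_constant_unchanged(self):
        assert np.allclose(smooth_timecourse(np.full(20, 0.7)), 0.7)

    def test_impulse_kernel(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = smooth_timecourse(x)
        assert np.allclose(out[3:8], 0.2)
        assert out[2] == 0.0

    def test_interior_matches_brute_force(self, rng):
        x = rng.random(30)
        out = smooth_timecourse(x)
        for i in range(2, 28):
            assert out[i] == pytest.approx(x[i - 2:i + 3].mean())

    def test_truncated_edges(self, rng):
        x = rng.random(10)
        out = smooth_timecourse(x)
        assert out[0] == pytest.approx(x[:3].mean())
        assert out[-1] == pytest.approx(x[-3:].mean())

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ConfigurationError):
            smooth_timecourse(np.zeros(3), 5)


def _signal_epochs(rng, n_per=18, n_ch=6, n_t=30, onset_idx=12, amp=4.0,
                   noise=1.0, template=None):
    """Two-condition epochs at 50 Hz with an opposite-polarity template
    switching on at ``onset_idx``."""
    if template is None:
        template = rng.normal(size=n_ch)
        template /= np.abs(template).max()
    data = rng.normal(0, noise, size=(2 * n_per, n_ch, n_t))
    box = np.zeros(n_t)
    box[onset_idx:] = 1.0
    sig = amp / 2 * template[:, None] * box[None, :]
    data[:n_per] += sig
    data[n_per:] -= sig
    cond = np.array(["cue_left"] * n_per + ["cue_right"] * n_per, dtype=object)
    ep = make_epochs(data, sfreq=50.0, start_ms=-200.0, condition=cond,
                     channels=[f"ch{i}" for i in range(n_ch)])
    return ep, template


class TestDecodeTimecourse:
    def test_attempts_count_default_config(self, rng):
        ep, _ = _signal_epochs(rng, n_per=9, n_t=6)
        tc = decode_timecourse(ep, DecoderConfig(seed=0, n_iterations=20))
        assert tc.n_attempts == 120

    def test_fixed_seed_bit_identical(self, rng):
        ep, _ = _signal_epochs(rng, n_per=9, n_t=8)
        a = decode_timecourse(ep, DecoderConfig(seed=3, n_iterations=4))
        b = decode_timecourse(ep, DecoderConfig(seed=3, n_iterations=4))
        assert np.array_equal(a.accuracy, b.accuracy)
        assert np.array_equal(a.activations, b.activations)
        c = decode_timecourse(ep, DecoderConfig(seed=4, n_iterations=4))
        assert not np.array_equal(a.accuracy, c.accuracy)

    def test_planted_onset_high_snr(self, rng):
        ep, _ = _signal_epochs(rng, amp=8.0, noise=0.3)
        tc = decode_timecourse(ep, DecoderConfig(seed=0, n_iterations=5))
        post = tc.accuracy[13:]
        pre = tc.accuracy[:11]
        assert post.mean() > 0.95
        assert abs(pre.mean() - 0.5) < 0.2

    def test_common_offset_invariance(self, rng):
        ep, _ = _signal_epochs(rng, n_per=9, n_t=8)
        shifted = ep.copy()
        shifted.data += 57.0  # same offset on every channel
        a = decode_timecourse(ep, DecoderConfig(seed=1, n_iterations=3))
        b = decode_timecourse(shifted, DecoderConfig(seed=1, n_iterations=3))
        assert np.allclose(a.accuracy, b.accuracy)

    def test_uniform_scaling_leaves_accuracy_and_normalized_maps(self, rng):
        ep, _ = _signal_epochs(rng, n_per=9, n_t=8)
        scaled = ep.copy()
        scaled.data *= 3.0
        a = decode_timecourse(ep, DecoderConfig(seed=1, n_iterations=3))
        b = decode_timecourse(scaled, DecoderConfig(seed=1, n_iterations=3))
        assert np.allclose(a.accuracy, b.accuracy)
        # z-scored features: maps agree up to solver round-off
        assert np.allclose(a.activations, b.activations, atol=1e-3)

    def test_activation_map_recovers_planted_template(self, rng):
        ep, template = _signal_epochs(rng, amp=6.0, noise=0.5)
        tc = decode_timecourse(ep, DecoderConfig(seed=0, n_iterations=5))
        post_map = tc.activations[15:].mean(axis=0)
        r = np.corrcoef(post_map, template)[0, 1]
        assert abs(r) > 0.9

    def test_monotone_in_effect_amplitude(self):
        means = []
        for amp in (0.5, 1.5, 4.0):
            accs = []
            for seed in range(3):
                ep, _ = _signal_epochs(np.random.default_rng(100 + seed),
                                       amp=amp, noise=1.5)
                tc = decode_timecourse(ep, DecoderConfig(seed=seed, n_iterations=4))
                accs.append(tc.accuracy[13:].mean())
            means.append(np.mean(accs))
        assert means[0] <= means[1] <= means[2]

    def test_more_than_two_conditions_rejected(self, rng):
        ep, _ = _signal_epochs(rng, n_per=9, n_t=6)
        ep.condition[0] = "other"
        with pytest.raises(DataError):
            decode_timecourse(ep)


class TestChannelSubset:
    def test_subset_of_all_equals_full(self, rng):
        ep, _ = _signal_epochs(rng, n_per=9, n_t=8)
        full = decode_timecourse(ep, DecoderConfig(seed=2, n_iterations=3))
        sub = channel_subset_decode(ep, tuple(ep.channels),
                                    DecoderConfig(seed=2, n_iterations=3))
        assert np.array_equal(full.accuracy, sub.accuracy)

    def test_missing_channel_raises(self, rng):
        ep, _ = _signal_epochs(rng, n_per=9, n_t=6)
        with pytest.raises(ChannelError):
            channel_subset_decode(ep, ("F7", "F8"))


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [{"n_groups": 1}, {"n_iterations": 0},
                                    {"smoothing_points": 4}])
    def test_invalid_config(self, kw):
        with pytest.raises(ConfigurationError):
            DecoderConfig(**kw)
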