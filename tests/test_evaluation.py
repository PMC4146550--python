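"""Accuracy, chance-level significance, ITR, cross-validation, screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hybridbci.eeg import Recording
from hybridbci.evaluation import (
    binary_accuracy,
    chance_test,
    chance_test_chi2,
    crossval_accuracy,
    itr_with_pauses,
    spectral_screening,
    wolpaw_bits,
)
from hybridbci.online import SessionLog, TrialOutcome


def make_log(corrects, trial_len=5.0, pause=3.0, decisions=None, cues=None):
    outcomes = []
    t = 0.0
    for i, c in enumerate(corrects):
        outcomes.append(
            TrialOutcome(
                cue=1 if cues is None else cues[i],
                accumulated=1.0 if c else -1.0,
                decision="sign" if decisions is None else decisions[i],
                correct=c,
                t_start=t,
                t_end=t + trial_len,
            )
        )
        t += trial_len + pause
    return SessionLog(outcomes=outcomes, mode="CopyTask",
                      pauses=(len(corrects) - 1) * pause)


class TestBinaryAccuracy:
    def test_all_correct(self):
        res = binary_accuracy(make_log([True] * 25))
        assert res.accuracy == 1.0
        assert res.n_correct == 25

    def test_fifteen_of_twenty(self):
        res = binary_accuracy(make_log([True] * 15 + [False] * 5))
        assert res.accuracy == pytest.approx(0.75)
        assert res.significant  # p ~ 0.0207 < 0.05

    def test_random_scorer_lands_near_chance(self):
        rng = np.random.default_rng(0)
        res = binary_accuracy(make_log(list(rng.random(1000) < 0.5)))
        assert 0.47 <= res.accuracy <= 0.53

    def test_blocks_of_at_least_twenty_trials(self):
        res = binary_accuracy(make_log([True] * 30 + [False] * 20))
        assert len(res.block_accuracies) == 2
        assert all(
            b == pytest.approx(v) for b, v in zip(res.block_accuracies, [1.0, 0.2])
        )

    def test_no_labeled_trials_flagged(self):
        log = make_log([True])
        log.outcomes[0].correct = None
        with pytest.raises(ValueError, match="labeled"):
            binary_accuracy(log)


class TestChanceTest:
    def test_fifteen_of_twenty_matches_bruteforce_tail(self):
        # sum_{k=15}^{20} C(20,k) / 2^20 = 21700/1048576
        assert chance_test(15, 20) == pytest.approx(21700 / 1048576, rel=1e-12)

    def test_ten_of_twenty_matches_bruteforce_tail(self):
        from math import comb

        expected = sum(comb(20, k) for k in range(10, 21)) / 2**20
        assert chance_test(10, 20) == pytest.approx(expected, rel=1e-12)
        assert chance_test(10, 20) == pytest.approx(0.588, abs=5e-4)

    def test_perfect_run_closed_form(self):
        assert chance_test(20, 20) == pytest.approx(2.0**-20, rel=1e-12)

    def test_monotone_in_correct_count(self):
        ps = [chance_test(k, 30) for k in range(31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_chi2_cross_check_agrees_on_significance_at_moderate_n(self):
        # both tests should call 15/20 significant and 10/20 not
        assert chance_test_chi2(15, 20) < 0.05
        assert chance_test_chi2(10, 20) > 0.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chance_test(5, 4)


class TestWolpawBits:
    def test_perfect_binary_selection_is_one_bit(self):
        assert wolpaw_bits(1.0, 2) == pytest.approx(1.0)

    def test_chance_is_zero_bits(self):
        assert wolpaw_bits(0.5, 2) == pytest.approx(0.0)

    def test_ninety_percent_accuracy(self):
        assert wolpaw_bits(0.9, 2) == pytest.approx(0.53101, abs=1e-5)

    def test_strictly_increasing_above_chance(self):
        ps = np.linspace(0.5, 1.0, 200)
        bits = np.array([wolpaw_bits(p) for p in ps])
        assert np.all(np.diff(bits) > 0)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.0, 1.0))
    def test_bounded_between_zero_and_one_bit_for_binary(self, p):
        assert -1e-12 <= wolpaw_bits(p, 2) <= 1.0 + 1e-12


class TestITR:
    def test_ten_perfect_decided_trials_in_five_minutes(self):
        # 10 bits in 5 min -> 2 bits/min
        log = make_log([True] * 10, trial_len=5.0, pause=(300.0 - 50.0) / 9)
        # stretch the last trial end so the span is exactly 300 s
        log.outcomes[-1].t_end = log.outcomes[0].t_start + 300.0
        assert itr_with_pauses(log) == pytest.approx(10.0 / 5.0, rel=1e-6)

    def test_nodecision_trials_dilute_the_rate(self):
        corrects = [True] * 10 + [None] * 5
        decisions = ["sign"] * 10 + ["noDecision"] * 5
        log = make_log(corrects, trial_len=5.0, pause=25.0, decisions=decisions)
        log.outcomes[-1].t_end = log.outcomes[0].t_start + 450.0
        assert itr_with_pauses(log) == pytest.approx(10.0 / 7.5, rel=1e-6)

    def test_zero_decided_trials_is_zero_rate(self):
        log = make_log([None] * 4, decisions=["noDecision"] * 4)
        assert itr_with_pauses(log) == 0.0

    def test_monotone_decreasing_in_added_pause(self):
        rates = []
        for extra in (0.0, 60.0, 120.0):
            log = make_log([True] * 10, pause=10.0)
            log.outcomes[-1].t_end += extra
            rates.append(itr_with_pauses(log))
        assert rates[0] > rates[1] > rates[2]


class TestCrossValidation:
    def test_separable_synthetic_epochs_score_high(self, synth_session):
        from hybridbci.eeg import epoch
        from hybridbci.preprocess import FilterSpec, bandpass
        from hybridbci.eeg import BandDefinition

        rec, _ = synth_session
        spec = FilterSpec("bandpass", BandDefinition(8.0, 12.0))
        ep = epoch(bandpass(rec, spec), ("class1", "class2"), (0.0, 5000.0))
        res = crossval_accuracy(ep, interval=(500.0, 4500.0), seed=0)
        assert res.mean_accuracy >= 0.95

    def test_label_shuffled_epochs_stay_at_chance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 4, 50))
        y = np.r_[np.ones(30, dtype=int), np.full(30, 2, dtype=int)]
        accs = []
        for _ in range(20):
            accs.append(crossval_accuracy(X, rng.permutation(y)).mean_accuracy)
        mean_acc = np.mean(accs)
        band = 1.96 * np.sqrt(0.25 / (60 * 20))
        assert 0.5 - band <= mean_acc <= 0.5 + band

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3, 50))
        y = np.r_[np.ones(20, dtype=int), np.full(20, 2, dtype=int)]
        a = crossval_accuracy(X, y, seed=5).fold_accuracies
        b = crossval_accuracy(X, y, seed=5).fold_accuracies
        np.testing.assert_array_equal(a, b)

    def test_fold_reduction_warns_on_few_trials(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((7, 8))
        y = np.array([1, 1, 1, 1, 2, 2, 2])
        with pytest.warns(UserWarning, match="reducing folds"):
            crossval_accuracy(X, y, n_folds=5)


class TestSpectralScreening:
    def test_planted_posterior_alpha_appears_only_eyes_closed(self):
        from hybridbci.synthetic import generate_screening_recording

        rec, segments = generate_screening_recording(seed=4)
        res = spectral_screening(rec, segments)
        posterior = [rec.channel_labels.index(c) for c in ("P3", "Pz", "P4")]
        for ch in posterior:
            assert res.alpha_power["eyes-closed"][ch] > 2 * res.alpha_power[
                "eyes-open"
            ][ch]

    def test_flat_generator_conditions_indistinguishable(self):
        from hybridbci.synthetic import generate_screening_recording

        rec, segments = generate_screening_recording(seed=5, no_idle_rhythm=True)
        res = spectral_screening(rec, segments)
        ratio = res.alpha_power["eyes-closed"] / res.alpha_power["eyes-open"]
        assert np.all(ratio < 1.6) and np.all(ratio > 0.6)

    def test_parseval_total_power_matches_variance(self):
        rng = np.random.default_rng(6)
        sig = rng.standard_normal((1, 65536))
        rec = Recording(sig, 100.0, ["a"])
        res = spectral_screening(rec, {"x": (0, 65536)}, nperseg=1024)
        power = np.trapezoid(res.spectra["x"][0], res.freqs)
        assert power == pytest.approx(sig.var(), rel=0.02)

    def test_short_segment_rejected(self):
        rec = Recording(np.zeros((1, 1000)), 100.0, ["a"])
        with pytest.raises(ValueError, match="shorter"):
            spectral_screening(rec, {"x": (0, 100)}, nperseg=256)
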