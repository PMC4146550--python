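"""Shrinkage LDA, adaptation, meta-combination and threshold gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridbci.classifiers import (
    NO_DECISION,
    AdaptationState,
    DecisionPolicy,
    LDAModel,
    MetaClassifier,
    ShrinkageLDA,
    adapt,
    calibrate_theta,
    combine,
    decide,
    lda_score,
    train_shrinkage_lda,
)


def gaussian_data(rng, n_per_class, mu1, mu2, cov=None):
    d = len(mu1)
    cov = np.eye(d) if cov is None else cov
    X = np.vstack(
        [
            rng.multivariate_normal(mu1, cov, size=n_per_class),
            rng.multivariate_normal(mu2, cov, size=n_per_class),
        ]
    )
    y = np.r_[np.ones(n_per_class, dtype=int), np.full(n_per_class, 2, dtype=int)]
    return X, y


class TestTraining:
    def test_identity_covariance_recovers_mean_difference_direction(self):
        rng = np.random.default_rng(0)
        X, y = gaussian_data(rng, 2000, [-1.0, 0.0], [1.0, 0.0])
        m = train_shrinkage_lda(X, y)
        w = m.w / np.linalg.norm(m.w)
        assert abs(w[0]) > 0.99
        assert abs(m.b) < 0.1
        assert lda_score(m, np.array([1.0, 0.0])) > 0
        assert lda_score(m, np.array([-1.0, 0.0])) < 0

    def test_gamma_one_is_nearest_mean_direction(self):
        rng = np.random.default_rng(1)
        cov = np.array([[4.0, 1.0], [1.0, 2.0]])
        X, y = gaussian_data(rng, 200, [-1.0, 0.5], [1.0, -0.5], cov)
        m = train_shrinkage_lda(X, y, gamma=1.0)
        nu = np.trace(m.sigma) / 2
        np.testing.assert_allclose(m.w, (m.mu2 - m.mu1) / nu, atol=1e-10)

    def test_high_dimensional_small_sample_is_regularized(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((5, 20))
        y = np.array([1, 1, 2, 2, 2])
        m = train_shrinkage_lda(X, y)
        assert m.gamma > 0
        assert np.all(np.isfinite(m.w))

    def test_constant_feature_survives_via_shrinkage(self):
        rng = np.random.default_rng(3)
        X, y = gaussian_data(rng, 20, [-1.0, 0.0], [1.0, 0.0])
        X[:, 1] = 5.0  # zero-variance feature
        m = train_shrinkage_lda(X, y)
        assert np.all(np.isfinite(m.w))

    def test_single_class_rejected(self):
        X = np.random.default_rng(4).standard_normal((10, 3))
        with pytest.raises(ValueError, match="both classes"):
            train_shrinkage_lda(X, np.ones(10, dtype=int))

    def test_matches_sklearn_shrinkage_lda(self):
        # independent route: sklearn lsqr solver with Ledoit-Wolf shrinkage
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(5)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        X, y = gaussian_data(rng, 60, [-1.0, 0.2], [1.0, -0.2], cov)
        ours = ShrinkageLDA().fit(X, y)
        theirs = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        theirs.fit(X, y)
        cos = ours.model_.w @ theirs.coef_[0] / (
            np.linalg.norm(ours.model_.w) * np.linalg.norm(theirs.coef_[0])
        )
        assert cos > 0.999
        # class-cov pooling details differ slightly; boundary points may flip
        assert np.mean(ours.predict(X) == theirs.predict(X)) >= 0.99


class TestScoring:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(6)
        X, y = gaussian_data(rng, 100, [-1.0, 0.0], [1.0, 0.3])
        return train_shrinkage_lda(X, y)

    def test_midpoint_scores_zero(self, model):
        mid = (model.mu1 + model.mu2) / 2
        assert lda_score(model, mid) == pytest.approx(0.0, abs=1e-10)

    def test_class_means_score_with_correct_signs(self, model):
        assert lda_score(model, model.mu2) > 0
        assert lda_score(model, model.mu1) < 0

    def test_affine_in_the_input(self, model):
        rng = np.random.default_rng(7)
        x, d = rng.standard_normal(2), rng.standard_normal(2)
        lhs = lda_score(model, x + d) - lda_score(model, x)
        assert lhs == pytest.approx(float(model.w @ d))

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="dim"):
            lda_score(model, np.zeros(5))

    def test_adding_constant_changes_bias_not_weights(self):
        rng = np.random.default_rng(8)
        X, y = gaussian_data(rng, 50, [-1.0, 0.0], [1.0, 0.0])
        m0 = train_shrinkage_lda(X, y)
        m1 = train_shrinkage_lda(X + 10.0, y)
        np.testing.assert_allclose(m0.w, m1.w, atol=1e-9)
        assert abs(m0.b - m1.b) > 1.0

    def test_gamma_to_zero_converges_to_plain_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(9)
        X, y = gaussian_data(rng, 250, [-0.5, 0.0, 0.0, 0.0, 0.0, 0.0],
                             [0.5, 0.1, 0.0, 0.0, 0.0, 0.0])
        ours = train_shrinkage_lda(X, y, gamma=1e-9)
        plain = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None).fit(X, y)
        pred = np.where(np.atleast_1d(lda_score(ours, X)) > 0, 2, 1)
        assert np.mean(pred == plain.predict(X)) > 0.995


class TestAdaptation:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(10)
        X, y = gaussian_data(rng, 20, [-1.0, 0.0], [1.0, 0.0])
        m = train_shrinkage_lda(X, y)
        out = adapt(m, AdaptationState(rate=0.0), rng.standard_normal(2), 1)
        np.testing.assert_array_equal(out.mu1, m.mu1)
        np.testing.assert_array_equal(out.sigma, m.sigma)
        np.testing.assert_array_equal(out.w, m.w)

    def test_default_rate_is_three_percent(self):
        assert AdaptationState().rate == 0.03

    def test_repeated_identical_samples_contract_geometrically(self):
        # ||mu1 - x*|| shrinks by (1 - eta)^n under n updates with x*
        rng = np.random.default_rng(11)
        X, y = gaussian_data(rng, 20, [-1.0, 0.0], [1.0, 0.0])
        m = train_shrinkage_lda(X, y)
        st = AdaptationState(rate=0.03)
        x_star = np.array([3.0, -2.0])
        d0 = np.linalg.norm(m.mu1 - x_star)
        n = 25
        for _ in range(n):
            m = adapt(m, st, x_star, 1)
        assert np.linalg.norm(m.mu1 - x_star) == pytest.approx(
            d0 * (1 - 0.03) ** n, rel=1e-9
        )
        assert st.n_updates == n

    def test_disabled_state_is_a_contract_violation(self):
        rng = np.random.default_rng(12)
        X, y = gaussian_data(rng, 20, [-1.0, 0.0], [1.0, 0.0])
        m = train_shrinkage_lda(X, y)
        with pytest.raises(RuntimeError, match="FreeMode"):
            adapt(m, AdaptationState(enabled=False), np.zeros(2), 1)

    def test_tracks_rotating_class_means(self):
        # the rationale for adaptation: frozen LDA decays under drift
        from hybridbci.synthetic import drifting_feature_stream

        benefits = []
        for seed in range(8):
            Xtr, ytr, Xs, ys = drifting_feature_stream(seed)
            frozen = train_shrinkage_lda(Xtr, ytr)
            adaptive = train_shrinkage_lda(Xtr, ytr)
            st = AdaptationState(rate=0.03)
            n_f = n_a = 0
            for x, lab in zip(Xs, ys):
                n_f += (lda_score(frozen, x) > 0) == (lab == 2)
                n_a += (lda_score(adaptive, x) > 0) == (lab == 2)
                adaptive = adapt(adaptive, st, x, lab)
            benefits.append((n_a - n_f) / len(ys))
        assert np.mean(benefits) >= 0.05


class TestMetaClassifier:
    def test_weights_normalized(self):
        m = MetaClassifier(weights=(2.0, 6.0))
        assert m.weights == (0.25, 0.75)

    def test_pure_oscillatory_weight_returns_that_score(self):
        m = MetaClassifier(weights=(1.0, 0.0))
        assert combine(m, 0.7, -3.0) == pytest.approx(0.7)

    def test_equal_scores_pass_through_any_weights(self):
        m = MetaClassifier(weights=(0.3, 0.7))
        assert combine(m, 1.3, 1.3) == pytest.approx(1.3)

    def test_scales_make_branches_commensurate(self):
        m = MetaClassifier(weights=(0.5, 0.5), scales=(2.0, 0.5))
        assert combine(m, 2.0, 0.5) == pytest.approx(1.0)

    def test_cv_weighting_ignores_below_chance_branch(self):
        m = MetaClassifier.from_cv_accuracies(0.9, 0.4)
        assert m.weights == (1.0, 0.0)

    def test_combined_at_least_as_good_as_best_single_branch(self):
        # both branches carry independent evidence; seed-averaged accuracy
        rng_master = np.random.default_rng(13)
        deltas = []
        for _ in range(20):
            rng = np.random.default_rng(rng_master.integers(2**31))
            y = rng.integers(1, 3, size=400)
            sgn = np.where(y == 2, 1.0, -1.0)
            s_osc = sgn + 1.2 * rng.standard_normal(400)
            s_slow = sgn + 1.2 * rng.standard_normal(400)
            meta = MetaClassifier(weights=(0.5, 0.5))
            s_comb = np.array(
                [combine(meta, a, b) for a, b in zip(s_osc, s_slow)]
            )
            acc = lambda s: np.mean((s > 0) == (y == 2))
            deltas.append(acc(s_comb) - max(acc(s_osc), acc(s_slow)))
        assert np.mean(deltas) >= -0.01


class TestDecide:
    def test_zero_threshold_sign_decision(self):
        p = DecisionPolicy(theta=0.0)
        assert decide(p, -0.2) == p.action_negative
        assert decide(p, 0.2) == p.action_positive

    def test_infinite_threshold_never_decides(self):
        p = DecisionPolicy(theta=np.inf)
        assert decide(p, 1e12) == NO_DECISION

    def test_boundary_maps_to_no_decision(self):
        p = DecisionPolicy(theta=0.5)
        assert decide(p, 0.5) == NO_DECISION
        assert decide(p, -0.5) == NO_DECISION

    @settings(derandomize=True, max_examples=200)
    @given(
        acc=st.floats(-10, 10, allow_nan=False),
        t1=st.floats(0, 5),
        t2=st.floats(0, 5),
    )
    def test_raising_theta_never_creates_a_decision(self, acc, t1, t2):
        lo, hi = sorted([t1, t2])
        d_lo = decide(DecisionPolicy(theta=lo), acc)
        d_hi = decide(DecisionPolicy(theta=hi), acc)
        if d_lo == NO_DECISION:
            assert d_hi == NO_DECISION
        elif d_hi != NO_DECISION:
            assert d_hi == d_lo

    def test_theta_calibration_reaches_target_precision(self):
        rng = np.random.default_rng(14)
        y = rng.integers(1, 3, size=300)
        acc = np.where(y == 2, 0.5, -0.5) + rng.standard_normal(300)
        theta = calibrate_theta(acc, y, target_precision=0.8)
        decided = np.abs(acc) > theta
        signs = np.where(y == 2, 1.0, -1.0)
        prec = np.mean(np.sign(acc[decided]) == signs[decided])
        assert prec >= 0.8


class TestSerialization:
    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(15)
        X, y = gaussian_data(rng, 30, [-1.0, 0.0], [1.0, 0.0])
        m = train_shrinkage_lda(X, y)
        m.to_json(tmp_path / "m.json")
        back = LDAModel.from_json(tmp_path / "m.json")
        x = rng.standard_normal(2)
        assert lda_score(back, x) == pytest.approx(lda_score(m, x))
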