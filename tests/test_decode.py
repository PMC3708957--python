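"""Regularized logistic decoding: optimizer contracts, grid search,
cross-validation structure and binomial significance."""

import numpy as np
import pytest
from scipy import stats

from erpdecode.decode import (
    LAMBDA_GRID,
    FeatureMatrix,
    binomial_threshold,
    crossval_cross_participant,
    crossval_within,
    grid_search_lambda,
    make_features,
    penalized_loss_grad,
    total_variance,
    train,
)
from erpdecode.synth import SynthConfig, render_participant

from conftest import make_epochs


def feature_matrix(X, y):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X=X,
        y=np.asarray(y),
        n_channels=1,
        n_samples=X.shape[1],
        channel_labels=("C01",),
        times=np.arange(X.shape[1], dtype=float),
    )


def gaussian_classes(rng, n_per_class, d, sep):
    """Two spherical Gaussians separated by `sep` along one axis."""
    mu = np.zeros(d)
    mu[0] = sep / 2.0
    X = np.vstack(
        [
            rng.normal(size=(n_per_class, d)) + mu,
            rng.normal(size=(n_per_class, d)) - mu,
        ]
    )
    y = np.array([1] * n_per_class + [-1] * n_per_class)
    return feature_matrix(X, y)


class TestTrain:
    def test_gradient_vanishes_at_optimum(self):
        rng = np.random.default_rng(0)
        feats = gaussian_classes(rng, 30, 40, sep=1.0)  # dual path (n < d)
        lam = 0.5 * total_variance(feats.X)
        model = train(feats, lam)
        _, gw, gb = penalized_loss_grad(
            model.w, model.b, feats.X, feats.y, lam
        )
        assert np.linalg.norm(np.concatenate([gw, [gb]])) < 1e-6

        feats_p = gaussian_classes(rng, 60, 10, sep=1.0)  # primal path
        model_p = train(feats_p, 1.0)
        _, gw, gb = penalized_loss_grad(
            model_p.w, model_p.b, feats_p.X, feats_p.y, 1.0
        )
        assert np.linalg.norm(np.concatenate([gw, [gb]])) < 1e-6

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 5))
        y = np.array([1, -1] * 6)
        w = rng.normal(size=5)
        b = 0.3
        lam = 0.7
        loss, gw, gb = penalized_loss_grad(w, b, X, y, lam)
        eps = 1e-6
        for j in range(5):
            dw = w.copy()
            dw[j] += eps
            lp, _, _ = penalized_loss_grad(dw, b, X, y, lam)
            assert gw[j] == pytest.approx((lp - loss) / eps, abs=1e-4)
        lp, _, _ = penalized_loss_grad(w, b + eps, X, y, lam)
        assert gb == pytest.approx((lp - loss) / eps, abs=1e-4)

    def test_symmetric_data_gives_null_weights(self):
        rng = np.random.default_rng(2)
        Xhalf = rng.normal(size=(25, 8))
        X = np.vstack([Xhalf, Xhalf])  # identical features, opposite labels
        y = np.array([1] * 25 + [-1] * 25)
        model = train(feature_matrix(X, y), lam=1.0)
        assert np.linalg.norm(model.w) < 1e-5
        p = model.predict_proba(X)
        np.testing.assert_allclose(p, 0.5, atol=1e-5)

    def test_ridge_shrinkage_limit(self):
        rng = np.random.default_rng(3)
        feats = gaussian_classes(rng, 25, 30, sep=2.0)
        tv = total_variance(feats.X)
        w_small = train(feats, 1.0).w
        w_huge = train(feats, 1e6 * tv).w
        assert np.linalg.norm(w_huge) < 1e-3 * np.linalg.norm(w_small)

    def test_decision_symmetry_under_negation(self):
        rng = np.random.default_rng(4)
        feats = gaussian_classes(rng, 20, 15, sep=1.5)
        model = train(feats, 1.0)
        flipped = feature_matrix(-feats.X, -feats.y)
        model_f = train(flipped, 1.0)
        np.testing.assert_allclose(
            model_f.decision_values(-feats.X),
            -model.decision_values(feats.X),
            atol=1e-4,
        )
        acc = np.mean(model.predict(feats.X) == feats.y)
        acc_f = np.mean(model_f.predict(-feats.X) == -feats.y)
        assert acc == pytest.approx(acc_f, abs=1e-12)

    def test_invalid_inputs(self):
        feats = feature_matrix(np.ones((4, 2)), [1, 1, 1, 1])
        with pytest.raises(ValueError):
            train(feats, 1.0)
        feats2 = feature_matrix(np.ones((4, 2)), [1, 1, -1, -1])
        with pytest.raises(ValueError):
            train(feats2, 0.0)


class TestGridSearch:
    def test_single_value_grid_returned(self):
        rng = np.random.default_rng(5)
        feats = gaussian_classes(rng, 20, 6, sep=1.0)
        lam = grid_search_lambda(feats, n_folds=3, grid=(0.1,))
        assert lam == pytest.approx(0.1 * total_variance(feats.X))

    def test_grid_membership(self):
        rng = np.random.default_rng(6)
        feats = gaussian_classes(rng, 25, 10, sep=1.0)
        lam = grid_search_lambda(feats, n_folds=4)
        tv = total_variance(feats.X)
        assert any(
            lam == pytest.approx(g * tv, rel=1e-12) for g in LAMBDA_GRID
        )

    def test_noisy_low_n_prefers_strong_shrinkage(self):
        # few trials, many features, weak signal: selected lambda should
        # sit at or above the grid median in most repeats
        rng = np.random.default_rng(7)
        chosen = []
        for _ in range(10):
            feats = gaussian_classes(rng, 12, 80, sep=0.3)
            tv = total_variance(feats.X)
            chosen.append(grid_search_lambda(feats, n_folds=3) / tv)
        assert np.median(chosen) >= 0.1


class TestCrossvalWithin:
    def test_folds_partition_trials(self, quiet_epochs):
        from erpdecode.preprocess import PreprocessConfig, run_preprocess

        windowed, _ = run_preprocess(
            quiet_epochs, PreprocessConfig(run_ica=False)
        )
        res = crossval_within(windowed, k=5, inner_folds=2, seed=0)
        orders = sorted(d.order for d in res.decisions)
        assert orders == sorted(windowed.trial_order.tolist())
        assert len(res.fold_accuracies) == 5

    def test_chance_level_on_null_features(self):
        rng = np.random.default_rng(8)
        n = 200
        feats = feature_matrix(
            rng.normal(size=(n, 20)),
            np.array([1, -1] * (n // 2)),
        )
        res = crossval_within(feats, k=10, inner_folds=3, seed=1)
        k_eq = res.mean_accuracy * n
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= k_eq <= hi

    def test_high_snr_recovers_signal(self):
        rng = np.random.default_rng(9)
        feats = gaussian_classes(rng, 50, 10, sep=4.0)  # Bayes rate ~0.98
        res = crossval_within(feats, k=10, inner_folds=3, seed=0)
        assert res.mean_accuracy > 0.9


class TestCrossParticipant:
    def _cohort(self, n_participants=4, seed0=50):
        cfg = SynthConfig(
            n_channels=8,
            sampling_rate=128.0,
            trial_count=120,
            noise_sd=2.0,
            artifact_rates={},
            seed=1,
        )
        from erpdecode.preprocess import PreprocessConfig, run_preprocess

        cohort = []
        for i in range(n_participants):
            ep = render_participant(
                cfg, "native", "19ms", seed0 + i, f"p{i:02d}"
            )
            w, _ = run_preprocess(ep, PreprocessConfig(run_ica=False))
            cohort.append(w)
        return cohort

    def test_leakage_audit_and_rates(self, monkeypatch):
        cohort = self._cohort()
        import erpdecode.decode as dec

        seen_folds = []
        orig = dec._grid_search_gram

        def spy(K, y, folds, tot_var, grid=LAMBDA_GRID):
            seen_folds.append(folds)
            return orig(K, y, folds, tot_var, grid)

        monkeypatch.setattr(dec, "_grid_search_gram", spy)
        res = crossval_cross_participant(
            cohort, trials_per_class=9, n_nested_folds=3, seed=0
        )
        assert len(res.rates) == len(cohort)
        assert all(0.0 <= r <= 1.0 for r in res.rates)
        # audit: for outer test participant i, none of its rows may appear
        # in any nested fold
        n_per = 18  # 9 per class
        for pi, folds in enumerate(seen_folds):
            test_rows = set(range(pi * n_per, (pi + 1) * n_per))
            for tr_idx, va_idx in folds:
                assert not test_rows & set(tr_idx.tolist())
                assert not test_rows & set(va_idx.tolist())

    def test_insufficient_trials_raise(self):
        cohort = self._cohort(3)
        with pytest.raises(ValueError, match="only"):
            crossval_cross_participant(cohort, trials_per_class=500)

    def test_too_few_participants(self):
        cohort = self._cohort(2)
        with pytest.raises(ValueError, match="participants"):
            crossval_cross_participant(cohort, trials_per_class=5)


class TestBinomialThreshold:
    @pytest.mark.parametrize("n", [50, 100, 200, 500])
    @pytest.mark.parametrize("alpha", [0.05, 0.01, 0.001])
    def test_matches_bruteforce_cdf_scan(self, n, alpha):
        # oracle: scan k upward accumulating the exact tail sum
        from math import comb

        def tail(k):
            return sum(
                comb(n, j) * 0.5**n for j in range(k, n + 1)
            )

        k_min = next(k for k in range(n + 1) if tail(k) <= alpha)
        assert binomial_threshold(n, alpha) == pytest.approx(k_min / n)

    def test_nonincreasing_in_n(self):
        ts = [binomial_threshold(n, 0.05) for n in range(50, 501, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(ts, ts[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_threshold(0, 0.05)
        with pytest.raises(ValueError):
            binomial_threshold(10, 0.0)


def test_make_features_shape_and_labels(quiet_epochs):
    from erpdecode.preprocess import PreprocessConfig, run_preprocess

    windowed, _ = run_preprocess(quiet_epochs, PreprocessConfig(run_ica=False))
    feats = make_features(windowed)
    # mastoids excluded: 8 scalp channels x 90 samples
    assert feats.X.shape[1] == 8 * 90
    assert set(feats.y.tolist()) == {-1, 1}
    assert "M1" not in feats.channel_labels
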