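"""Windowing, training dynamics, hybrid prediction and error-scale estimation."""

import numpy as np
import pytest
from sklearn.preprocessing import MinMaxScaler

from ndicube.cube import GapCube
from ndicube.clustering import cluster_sites
from ndicube.lstm import (
    PROV_FALLBACK,
    PROV_OBSERVED,
    PROV_RECYCLED,
    LSTMConfig,
    LSTMNetwork,
    estimate_sigma_lstm,
    impute_lstm,
    linear_interpolate,
    make_windows,
    predict_hybrid,
    train_cluster_model,
)


class TestMakeWindows:
    def test_pair_count(self):
        ws = make_windows(np.arange(100.0), window=12)
        assert ws.n_pairs == 88

    def test_chronological_split_no_leakage(self):
        ws = make_windows(np.arange(100.0), window=12, val_fraction=0.2)
        assert len(ws.val_targets) == round(0.2 * 88)
        assert ws.train_targets.max() < ws.val_targets.min()
        assert np.all(np.diff(ws.train_targets) > 0)
        assert np.all(np.diff(ws.val_targets) > 0)

    def test_window_equals_length_raises(self):
        with pytest.raises(ValueError):
            make_windows(np.arange(12.0), window=12)

    def test_inputs_precede_targets(self):
        series = np.arange(30.0)
        ws = make_windows(series, window=5)
        # each input window is exactly the 5 values before its target
        np.testing.assert_array_equal(ws.X_train[0], series[:5])
        assert ws.y_train[0] == series[5]


class TestNetworkGradients:
    def test_bptt_gradients_match_finite_differences(self):
        net = LSTMNetwork(hidden=5, seed=3)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 7))
        y = rng.normal(size=4)
        _, grads = net._gradients(X, y)
        eps = 1e-6
        for p, g in zip([net.Wx, net.Wh, net.b, net.Wy, net.by], grads):
            flat = p.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = net.loss(X, y)
                flat[idx] = orig - eps
                lm = net.loss(X, y)
                flat[idx] = orig
                assert g.ravel()[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


class TestTraining:
    def _scaled_sinusoid(self, T=200, period=40, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        series = 0.4 + 0.25 * np.sin(2 * np.pi * np.arange(T) / period)
        series = series + rng.normal(0, noise, T)
        sc = MinMaxScaler().fit(series[: int(0.8 * T)].reshape(-1, 1))
        return sc.transform(series.reshape(-1, 1)).ravel()

    def test_learns_sinusoid_better_than_mean_baseline(self):
        s = self._scaled_sinusoid()
        cfg = LSTMConfig(seed=0)
        net, hist = train_cluster_model(s, cfg)
        ws = make_windows(s, cfg.window, cfg.val_fraction)
        baseline = float(np.mean((ws.y_val - ws.y_train.mean()) ** 2))
        assert min(hist.val_loss) < baseline

    def test_same_seed_identical_history(self):
        s = self._scaled_sinusoid(noise=0.02)
        cfg = LSTMConfig(seed=7)
        _, h1 = train_cluster_model(s, cfg)
        _, h2 = train_cluster_model(s, cfg)
        assert h1.val_loss == h2.val_loss
        assert h1.train_loss == h2.train_loss

    def test_early_stopping_after_patience_stagnant_epochs(self):
        # zero learning rate: the validation loss can never improve after
        # the first epoch, so training must stop after exactly `patience`
        # stagnant epochs and keep the initial weights as best.
        s = self._scaled_sinusoid(noise=0.05)
        cfg = LSTMConfig(seed=0, learning_rate=0.0, patience=5, max_epochs=50)
        net, hist = train_cluster_model(s, cfg)
        assert len(hist.val_loss) == 1 + cfg.patience
        assert hist.best_epoch == 0

    def test_best_weights_restored(self):
        s = self._scaled_sinusoid(noise=0.02, seed=5)
        cfg = LSTMConfig(seed=1)
        net, hist = train_cluster_model(s, cfg)
        ws = make_windows(s, cfg.window, cfg.val_fraction)
        assert net.loss(ws.X_val, ws.y_val) == pytest.approx(min(hist.val_loss), rel=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            train_cluster_model(np.full(100, 0.5), LSTMConfig())


class TestPredictHybrid:
    def _setup(self, gaps=(), T=120, period=24, seed=0):
        rng = np.random.default_rng(seed)
        series = 0.4 + 0.25 * np.sin(2 * np.pi * np.arange(T) / period)
        series = np.clip(series + rng.normal(0, 0.01, T), -1, 1)
        cfg = LSTMConfig(seed=0)
        sc = MinMaxScaler().fit(series[: int(0.8 * T)].reshape(-1, 1))
        net, _ = train_cluster_model(sc.transform(series.reshape(-1, 1)).ravel(), cfg)
        gapped = series.copy()
        for g in gaps:
            gapped[g] = np.nan
        return gapped, net, sc, cfg

    def test_fully_observed_inputs_flagged_observed(self):
        series, net, sc, cfg = self._setup()
        imp = predict_hybrid(series, net, sc, cfg)
        assert (imp.provenance == PROV_OBSERVED).all()
        assert np.isfinite(imp.estimate).all()

    def test_interior_gap_recycles_prediction(self):
        series, net, sc, cfg = self._setup(gaps=[60])
        imp = predict_hybrid(series, net, sc, cfg)
        assert imp.provenance[60] == PROV_RECYCLED
        assert np.isfinite(imp.estimate[60])

    def test_leading_gap_uses_fallback(self):
        series, net, sc, cfg = self._setup(gaps=[range(0, 8)])
        imp = predict_hybrid(series, net, sc, cfg)
        assert (imp.provenance[:8] == PROV_FALLBACK).all()

    def test_all_missing_pixel_rejected(self):
        series, net, sc, cfg = self._setup()
        with pytest.raises(ValueError, match="no valid dates"):
            predict_hybrid(np.full(len(series), np.nan), net, sc, cfg)


class TestLinearInterpolate:
    def test_bridges_interior_and_extends_ends(self):
        y = np.array([np.nan, 1.0, np.nan, 3.0, np.nan])
        out = linear_interpolate(y)
        np.testing.assert_allclose(out, [1.0, 1.0, 2.0, 3.0, 3.0])

    def test_fully_missing_raises(self):
        with pytest.raises(ValueError):
            linear_interpolate(np.full(5, np.nan))


class TestSigmaLSTM:
    def test_perfect_predictions_zero(self):
        y = np.linspace(0, 1, 20)
        assert estimate_sigma_lstm(y, y, min_residuals=5) == 0.0

    def test_symmetric_residuals_population_sd(self):
        obs = np.zeros(12)
        est = np.array([0.05, -0.05] * 6)
        assert estimate_sigma_lstm(est, obs, min_residuals=5) == pytest.approx(0.05)

    def test_few_pairs_uses_cluster_pool(self):
        est = np.array([0.1, np.nan, np.nan])
        obs = np.array([0.0, np.nan, np.nan])
        pool = np.array([0.02, -0.02, 0.02, -0.02])
        assert estimate_sigma_lstm(est, obs, min_residuals=10, pool=pool) == pytest.approx(0.02)

    def test_no_residuals_anywhere_raises(self):
        with pytest.raises(ValueError):
            estimate_sigma_lstm(np.array([np.nan]), np.array([np.nan]))


class TestClusterImputation:
    def test_beats_seasonal_naive_on_shared_dynamics(self):
        # members share the reference's dynamics plus noise; one-step LSTM
        # predictions at observed dates should beat the value-at-(t-s) naive
        rng = np.random.default_rng(11)
        T, period = 365, 73
        base = 0.4 + 0.25 * np.sin(2 * np.pi * np.arange(T) / period) + 1.5e-4 * (
            np.arange(T) - T / 2
        )
        vals = np.empty((T, 1, 3))
        for j in range(3):
            vals[:, 0, j] = np.clip(base + rng.normal(0, 0.0104, T), -1, 1)
        cube = GapCube(values=vals, time_days=np.arange(T) * 5.0)
        assignment = cluster_sites(cube, min_cluster=2)
        assert assignment.n_clusters == 1
        cfg = LSTMConfig(seed=0)
        imp = impute_lstm(cube, assignment, cfg)
        for j in range(3):
            y = vals[:, 0, j]
            lstm_mae = np.abs(imp.estimate[cfg.window :, 0, j] - y[cfg.window :]).mean()
            naive_mae = np.abs(y[period:] - y[:-period]).mean()
            assert lstm_mae < naive_mae

    def test_small_cluster_falls_back_to_infinite_sigma(self, rng):
        T = 60
        vals = np.clip(rng.normal(0.3, 0.2, size=(T, 2, 2)), -1, 1)
        cube = GapCube(values=vals, time_days=np.arange(T, dtype=float))
        assignment = cluster_sites(cube, threshold=1.0, min_cluster=5)  # all singletons
        imp = impute_lstm(cube, assignment, LSTMConfig(seed=0))
        assert np.isinf(imp.sigma_lstm).all()
        assert not any(imp.trained.values())
        assert np.isfinite(imp.estimate).all()

    def test_estimates_defined_everywhere_with_gaps(self, small_synthetic):
        cube = small_synthetic.cube
        assignment = cluster_sites(cube)
        imp = impute_lstm(cube, assignment, LSTMConfig(seed=0))
        assert np.isfinite(imp.estimate).all()
        trained_any = any(imp.trained.values())
        assert trained_any
        finite_sigma = np.isfinite(imp.sigma_lstm)
        assert (imp.sigma_lstm[finite_sigma] >= 0).all()
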