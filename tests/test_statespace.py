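"""State-space construction, missing-data filtering/smoothing and imputation.

The filter and smoother are checked against an exact joint-Gaussian
conditioning oracle (tests/_oracle.py) and, independently, against the
fixed-parameter structural model of statsmodels.
"""

import numpy as np
import pytest

from _oracle import conditioned_signal_moments
from ndicube.cube import GapCube
from ndicube.statespace import (
    StateSpaceParams,
    build_state_space,
    derive_noise_params,
    impute_kf,
    impute_series,
    kalman_filter,
    reliability,
    rts_smooth,
    smooth_series,
)


class TestDeriveNoiseParams:
    def test_fixed_scales_are_the_operational_constants(self):
        p = derive_noise_params(np.array([0.2, 0.4, 0.6]))
        assert p.theta3 == 0.0011
        assert p.theta4 == 0.0104

    def test_level_and_slope_scales_from_series_mean(self):
        p = derive_noise_params(np.array([0.3, 0.3, np.nan, 0.3]))
        assert p.theta1 == pytest.approx(0.07 * 0.3 / 3)
        assert p.theta2 == pytest.approx(p.theta1 / 5)
        assert p.series_mean == pytest.approx(0.3)

    def test_zero_mean_series_is_degenerate_but_legal(self):
        p = derive_noise_params(np.array([0.2, -0.2]))
        assert p.theta1 == 0.0 and p.theta2 == 0.0

    def test_rms_option(self):
        p = derive_noise_params(np.array([0.3, -0.3]), use_rms=True)
        assert p.series_mean == pytest.approx(0.3)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            derive_noise_params(np.array([np.nan, np.nan]))

    def test_recompute_theta4_uses_radiometric_propagation(self):
        y = np.array([0.0, 0.0])
        p = derive_noise_params(y, recompute_theta4=True)
        assert p.theta4 == pytest.approx(0.015 / np.sqrt(2))


class TestBuildStateSpace:
    def test_state_dimension_is_period_plus_one(self):
        sys73 = build_state_space(StateSpaceParams(theta1=0.01, theta2=0.002, s=73))
        assert sys73.state_dim == 74
        assert sys73.transition.shape == (74, 74)

    def test_level_fixed_point_without_slope_or_season(self):
        system = build_state_space(StateSpaceParams(theta1=0.0, theta2=0.0, theta3=0.0, s=4))
        state = np.zeros(system.state_dim)
        state[0] = 0.42
        out = system.transition @ state
        np.testing.assert_allclose(out, state)

    def test_seasonal_block_sum_stays_zero_under_noiseless_transition(self):
        s = 5
        system = build_state_space(
            StateSpaceParams(theta1=0.0, theta2=0.0, theta3=0.0, theta4=0.0, s=s)
        )
        rng = np.random.default_rng(0)
        block = rng.normal(size=s - 1)
        state = np.zeros(system.state_dim)
        state[2:] = block
        seasonal = [state[2]]
        for _ in range(3 * s):
            state = system.transition @ state
            seasonal.append(state[2])
        seasonal = np.array(seasonal)
        # any s consecutive seasonal values sum to -oldest of the initial
        # block at the seam, and exactly 0 once the recursion owns the block
        roll = np.convolve(seasonal, np.ones(s), mode="valid")
        np.testing.assert_allclose(roll[s:], 0.0, atol=1e-12)

    def test_disturbance_covariance_diagonal(self):
        p = StateSpaceParams(theta1=0.01, theta2=0.002, theta3=0.003, theta4=0.02, s=4)
        system = build_state_space(p)
        diag = np.diag(system.state_cov)
        np.testing.assert_allclose(diag[:3], [0.01**2, 0.002**2, 0.003**2])
        assert np.count_nonzero(system.state_cov) == 3
        assert system.obs_var == pytest.approx(0.02**2)

    def test_variance_interpretation_flag(self):
        p = StateSpaceParams(theta1=0.01, theta2=0.002, s=4, as_variance=True)
        assert build_state_space(p).state_cov[0, 0] == pytest.approx(0.01)


def _random_instance(rng):
    s = int(rng.integers(3, 8))
    T = int(rng.integers(8, 31))
    p = StateSpaceParams(
        theta1=0.02 * rng.random() + 1e-3,
        theta2=0.01 * rng.random() + 1e-4,
        theta3=0.005 * rng.random() + 1e-4,
        theta4=0.02 * rng.random() + 1e-3,
        s=s,
    )
    y = rng.normal(0.4, 0.15, T)
    y[rng.random(T) < rng.uniform(0.2, 0.6)] = np.nan
    if np.isfinite(y).sum() < 2:
        y[:2] = 0.4
    return p, np.clip(y, -1, 1)


class TestOracleEquivalence:
    """Filter and smoother must equal exact joint-Gaussian conditioning."""

    def test_smoother_matches_oracle_on_random_instances(self, rng):
        for _ in range(10):
            p, y = _random_instance(rng)
            system = build_state_space(p)
            m = system.state_dim
            a0 = np.zeros(m)
            a0[0] = y[np.isfinite(y)][0]
            P0 = np.eye(m)
            sm = rts_smooth(kalman_filter(y, system, init_state=a0, init_cov=P0))
            om, ov = conditioned_signal_moments(y, system, a0, P0)
            np.testing.assert_allclose(sm.signal_mean(), om, atol=1e-8)
            np.testing.assert_allclose(sm.signal_var(), ov, atol=1e-8)

    def test_filter_matches_truncated_conditioning(self, rng):
        p, y = _random_instance(rng)
        system = build_state_space(p)
        m = system.state_dim
        a0 = np.zeros(m)
        a0[0] = y[np.isfinite(y)][0]
        P0 = np.eye(m)
        filt = kalman_filter(y, system, init_state=a0, init_cov=P0)
        T = len(y)
        for t in (0, T // 2, T - 1):
            yt = y.copy()
            yt[t + 1 :] = np.nan
            om, ov = conditioned_signal_moments(yt, system, a0, P0)
            assert filt.signal_mean("filtered")[t] == pytest.approx(om[t], abs=1e-8)
            assert filt.signal_var("filtered")[t] == pytest.approx(ov[t], abs=1e-8)

    def test_single_gap_smoothed_variance_below_filter_prediction(self, rng):
        p = StateSpaceParams(theta1=0.01, theta2=0.002, theta3=0.003, theta4=0.01, s=4)
        system = build_state_space(p)
        y = 0.4 + 0.1 * np.sin(2 * np.pi * np.arange(20) / 4)
        y[10] = np.nan
        filt = kalman_filter(y, system)
        sm = rts_smooth(filt)
        assert sm.signal_var()[10] < filt.signal_var("predicted")[10]


class TestFilterContracts:
    def test_fully_missing_series_follows_prior_with_growing_variance(self):
        p = StateSpaceParams(theta1=0.01, theta2=0.002, s=4)
        system = build_state_space(p)
        filt = kalman_filter(np.full(15, np.nan), system)
        var = filt.signal_var("predicted")
        assert np.all(np.diff(var) >= -1e-9)

    def test_variance_nondecreasing_across_missing_blocks(self, rng):
        # gap after the filter has seen several full cycles; before that the
        # diffuse seasonal prior rotates unequal per-state variances through
        # the signal and the monotone-growth regime is not yet reached
        for _ in range(5):
            s = int(rng.integers(3, 8))
            p = StateSpaceParams(
                theta1=0.02 * rng.random() + 1e-3,
                theta2=0.01 * rng.random() + 1e-4,
                theta3=0.005 * rng.random() + 1e-4,
                theta4=0.02 * rng.random() + 1e-3,
                s=s,
            )
            T = 60
            y = 0.4 + 0.2 * np.sin(2 * np.pi * np.arange(T) / s)
            y = y + rng.normal(0, 0.02, T)
            y[25:46] = np.nan
            filt = kalman_filter(y, build_state_space(p))
            var = filt.signal_var("predicted")[25:46]
            assert np.all(np.diff(var) >= -1e-9)

    def test_constant_series_zero_process_noise_converges(self):
        p = StateSpaceParams(theta1=0.0, theta2=0.0, theta3=0.0, theta4=0.01, s=4)
        y = np.full(60, 0.37)
        filt = kalman_filter(y, build_state_space(p))
        assert filt.signal_mean("filtered")[-1] == pytest.approx(0.37, abs=1e-3)
        assert filt.signal_var("filtered")[-1] < filt.signal_var("filtered")[5]

    def test_infinite_observation_rejected(self):
        p = StateSpaceParams(theta1=0.01, theta2=0.002, s=4)
        y = np.zeros(10)
        y[3] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            kalman_filter(y, build_state_space(p))

    def test_smoothed_equals_filtered_at_last_step(self, rng):
        p, y = _random_instance(rng)
        filt = kalman_filter(y, build_state_space(p))
        sm = rts_smooth(filt)
        np.testing.assert_allclose(sm.smoothed_mean[-1], filt.filtered_mean[-1])
        np.testing.assert_allclose(sm.smoothed_cov[-1], filt.filtered_cov[-1])

    def test_smoothing_never_increases_signal_variance(self, rng):
        p, y = _random_instance(rng)
        filt = kalman_filter(y, build_state_space(p))
        sm = rts_smooth(filt)
        assert np.all(sm.signal_var() <= filt.signal_var("filtered") + 1e-9)


class TestStatsmodelsCrossCheck:
    def test_matches_fixed_parameter_structural_model(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        T, s = 60, 6
        p = StateSpaceParams(theta1=0.008, theta2=0.002, theta3=0.003, theta4=0.012, s=s)
        y = 0.4 + 0.2 * np.sin(2 * np.pi * np.arange(T) / s) + rng.normal(0, 0.02, T)
        y[rng.random(T) < 0.3] = np.nan

        mod = sm.tsa.UnobservedComponents(y, level="lltrend", seasonal=s)
        v1, v2, v3, v4 = p.variances()
        a0 = np.zeros(mod.k_states)
        a0[0] = y[np.isfinite(y)][0]
        mod.ssm.initialize_known(a0, np.eye(mod.k_states) * 1e2)
        res = mod.smooth([v4, v1, v2, v3])
        Z = mod.ssm["design"][0, :]
        ref_mean = res.smoothed_state.T @ Z
        ref_var = np.einsum("i,ijt,j->t", Z, res.smoothed_state_cov, Z)

        mine = smooth_series(y, build_state_space(p))
        np.testing.assert_allclose(mine.signal_mean(), ref_mean, atol=1e-7)
        np.testing.assert_allclose(mine.signal_var(), ref_var, atol=1e-6)


class TestReliability:
    def test_mean_of_variances(self):
        assert reliability(np.array([1e-4, 2e-4, 3e-4])) == pytest.approx(2e-4)
        assert reliability(np.full(5, 0.3)) == pytest.approx(0.3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            reliability(np.array([]))


class TestImputation:
    def test_observed_dates_pass_through_unchanged(self, rng):
        p = StateSpaceParams(theta1=0.005, theta2=0.001, s=6)
        y = 0.4 + 0.2 * np.sin(2 * np.pi * np.arange(40) / 6) + rng.normal(0, 0.01, 40)
        y = np.clip(y, -1, 1)
        y[10:18] = np.nan
        imp = impute_series(y, p)
        obs = np.isfinite(y)
        np.testing.assert_array_equal(imp.combined_series[obs], y[obs])
        assert np.isfinite(imp.combined_series).all()

    def test_band_accounts_for_observation_noise(self, rng):
        p = StateSpaceParams(theta1=0.005, theta2=0.001, s=6)
        y = np.clip(0.4 + rng.normal(0, 0.01, 30), -1, 1)
        imp = impute_series(y, p)
        expect = 1.959963984540054 * np.sqrt(imp.p_k + p.theta4**2)
        np.testing.assert_allclose(imp.band_halfwidth, expect, rtol=1e-9)
        assert np.all(imp.ci_low <= imp.estimate) and np.all(imp.estimate <= imp.ci_high)

    def test_reliability_is_time_mean_of_variances(self, rng):
        p = StateSpaceParams(theta1=0.005, theta2=0.001, s=6)
        y = np.clip(0.4 + rng.normal(0, 0.01, 30), -1, 1)
        imp = impute_series(y, p)
        assert imp.reliability == pytest.approx(imp.p_k.mean())

    def test_under_two_valid_dates_flagged_degenerate(self):
        p = StateSpaceParams(theta1=0.005, theta2=0.001, s=6)
        y = np.full(20, np.nan)
        y[4] = 0.3
        imp = impute_series(y, p)
        assert imp.degenerate
        assert np.isfinite(imp.combined_series).all()
        assert imp.combined_series[4] == 0.3
        assert np.all(imp.p_k >= 1e2)

    def test_cube_imputation_shapes_and_passthrough(self, small_synthetic):
        cube = small_synthetic.cube
        out = impute_kf(cube, s=24)
        assert out.estimate.shape == cube.shape
        obs = cube.mask
        np.testing.assert_array_equal(out.combined[obs], cube.values[obs])
        assert np.isfinite(out.combined).all()
        assert np.all(out.p_k >= 0)
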