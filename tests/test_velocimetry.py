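"""Unit and property tests for g2 estimation, the Siegert fit and Eq.-2 conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ciliaspeckle.velocimetry import (
    Correlogram,
    SpeckleStack,
    estimate_g2,
    fit_siegert,
    tau_to_velocity,
    velocity_map_stack,
    window_start_indices,
)


def make_correlogram(beta, tau_c, lags, n_samples=18, n_exponent=1.0):
    g2 = 1.0 + beta * np.exp(-2.0 * (lags / tau_c) ** n_exponent)
    return Correlogram(lags=lags, g2_values=g2, n_samples_per_lag=np.full(len(lags), n_samples))


class TestEstimateG2:
    def test_alternating_series_hand_computed(self):
        # I = [2,0,2,0,2,0,2,0]: mean 1; lag-1 products all 0; lag-2 mean 2
        corr = estimate_g2(np.array([2.0, 0, 2, 0, 2, 0, 2, 0]), max_lag_frames=2)
        assert corr.g2_values == pytest.approx([0.0, 2.0])
        assert list(corr.n_samples_per_lag) == [7, 6]

    def test_constant_series_is_flat_unity(self):
        corr = estimate_g2(np.full(20, 3.7), max_lag_frames=5)
        assert corr.flat
        assert corr.g2_values == pytest.approx(np.ones(5))

    def test_all_zero_window_raises(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_g2(np.zeros(20), max_lag_frames=5)

    def test_lag_axis_uses_frame_rate(self):
        corr = estimate_g2(np.arange(1.0, 21.0), max_lag_frames=4, frame_rate=3000.0)
        assert corr.lags[0] == pytest.approx(1 / 3000.0)
        assert np.all(np.diff(corr.lags) > 0)

    @given(scale=st.floats(min_value=0.1, max_value=1e4))
    def test_intensity_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        x = rng.exponential(1.0, size=40)
        a = estimate_g2(x, 8).g2_values
        b = estimate_g2(scale * x, 8).g2_values
        assert a == pytest.approx(b, rel=1e-9)


class TestSiegertFit:
    @pytest.mark.parametrize("beta", [0.1, 0.5, 1.0])
    @pytest.mark.parametrize("tau_c", [2e-4, 2e-3, 2e-2])
    def test_noiseless_roundtrip(self, beta, tau_c):
        """Exact model samples recover (beta, tau_c) far below 0.1% error."""
        lags = tau_c * np.linspace(0.2, 3.0, 10)
        fit = fit_siegert(make_correlogram(beta, tau_c, lags))
        assert fit.valid
        assert abs(fit.beta - beta) / beta < 1e-3
        assert abs(fit.tau_c - tau_c) / tau_c < 1e-3

    def test_noiseless_roundtrip_stretched_exponent(self):
        lags = 2e-3 * np.linspace(0.2, 3.0, 12)
        fit = fit_siegert(make_correlogram(0.8, 2e-3, lags, n_exponent=1.5), n_exponent=1.5)
        assert abs(fit.tau_c - 2e-3) / 2e-3 < 1e-3

    def test_flat_correlogram_invalid_no_decay(self):
        corr = Correlogram(
            lags=np.arange(1, 11) / 3000.0,
            g2_values=np.full(10, 1.8),
            n_samples_per_lag=np.full(10, 18),
        )
        fit = fit_siegert(corr)
        assert not fit.valid

    def test_all_g2_below_one_invalid_not_exception(self):
        corr = Correlogram(
            lags=np.arange(1, 11) / 3000.0,
            g2_values=np.full(10, 0.97),
            n_samples_per_lag=np.full(10, 18),
        )
        fit = fit_siegert(corr)
        assert not fit.valid
        assert fit.reason == "no_decay"

    def test_too_few_lags_raises(self):
        corr = Correlogram(
            lags=np.array([1e-3, 2e-3]),
            g2_values=np.array([1.5, 1.2]),
            n_samples_per_lag=np.array([10, 9]),
        )
        with pytest.raises(ValueError):
            fit_siegert(corr)

    def test_beta_never_exceeds_one(self):
        # data generated with amplitude 1.3 still yields a physical beta
        lags = np.linspace(2e-4, 3e-3, 10)
        g2 = 1 + 1.3 * np.exp(-2 * lags / 1e-3)
        corr = Correlogram(lags=lags, g2_values=g2, n_samples_per_lag=np.full(10, 18))
        fit = fit_siegert(corr)
        assert fit.beta <= 1.0

    def test_agrees_with_scipy_curve_fit_on_noisy_data(self):
        """Independent optimizer cross-check: the vectorized Gauss-Newton
        fit and scipy's Levenberg-Marquardt land on the same optimum."""
        from scipy.optimize import curve_fit

        rng = np.random.default_rng(42)
        tau_true = 1.5e-3
        lags = tau_true * np.linspace(0.2, 3.0, 12)
        g2 = 1 + 0.8 * np.exp(-2 * lags / tau_true) + rng.normal(0, 0.01, 12)
        weights = np.full(12, 18.0)
        corr = Correlogram(lags=lags, g2_values=np.clip(g2, 0, None), n_samples_per_lag=weights)
        ours = fit_siegert(corr)

        def model(tau_ax, beta, tau_c):
            return 1 + beta * np.exp(-2 * tau_ax / tau_c)

        popt, _ = curve_fit(
            model, lags, corr.g2_values, p0=[0.5, 1e-3],
            sigma=1 / np.sqrt(weights), bounds=([1e-6, 1e-6], [1.0, 1.0]),
        )
        assert ours.beta == pytest.approx(popt[0], rel=1e-4)
        assert ours.tau_c == pytest.approx(popt[1], rel=1e-4)

    @given(
        beta=st.floats(min_value=0.1, max_value=1.0),
        log_tau=st.floats(min_value=-4.0, max_value=-2.0),
    )
    def test_roundtrip_property(self, beta, log_tau):
        tau_c = 10.0 ** log_tau
        lags = tau_c * np.linspace(0.25, 2.5, 10)
        fit = fit_siegert(make_correlogram(beta, tau_c, lags))
        assert abs(fit.tau_c - tau_c) / tau_c < 1e-3


class TestTauToVelocity:
    def test_worked_example(self):
        # 405 nm / (pi * 1.0 * 1.2892e-4 s) = 1.000 mm/s
        assert tau_to_velocity(1.2892e-4, 405.0, 1.0) == pytest.approx(1.0, abs=5e-4)

    def test_inverse_proportionality(self):
        v1 = tau_to_velocity(2e-3, 405.0, 1.0)
        v2 = tau_to_velocity(1e-3, 405.0, 1.0)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_long_tau_limit_vanishes(self):
        assert tau_to_velocity(1e12, 405.0, 1.0) < 1e-12

    def test_nonpositive_tau_raises(self):
        with pytest.raises(ValueError):
            tau_to_velocity(0.0, 405.0, 1.0)


class TestWindowing:
    def test_3000_frames_default_settings_give_300_windows(self):
        starts = window_start_indices(3000, 20, 10, 10)
        assert len(starts) == 300
        assert starts[0] == 0 and starts[-1] == 2990

    @pytest.mark.parametrize(
        "n,window,stride,expected_last",
        [(100, 20, 10, 90), (60, 20, 20, 40), (45, 20, 10, 40)],
    )
    def test_truncation_convention(self, n, window, stride, expected_last):
        starts = window_start_indices(n, window, stride, window // 2)
        assert starts[-1] == expected_last
        # every kept window supports at least 3 lags
        assert all(min(window, n - s) >= 5 for s in starts)

    def test_velocity_map_shapes_and_timestamps(self):
        rng = np.random.default_rng(2)
        frames = rng.exponential(1.0, size=(80, 4, 4))
        stack = SpeckleStack(frames, 3000.0, 0.1833, 405.0, 1.0)
        vs = velocity_map_stack(stack)
        assert vs.n_windows == len(window_start_indices(80, 20, 10, 10))
        assert np.all(np.diff(vs.timestamps) > 0)
        assert vs.timestamps[0] == pytest.approx(9.5 / 3000.0)

    def test_static_stack_fully_masked(self):
        frames = np.ones((60, 4, 4)) * 7.0
        stack = SpeckleStack(frames, 3000.0, 0.1833, 405.0, 1.0)
        vs = velocity_map_stack(stack)
        assert not vs.valid.any()

    def test_stack_shorter_than_window_raises(self):
        frames = np.ones((10, 4, 4))
        stack = SpeckleStack(frames, 3000.0, 0.1833, 405.0, 1.0)
        with pytest.raises(ValueError):
            velocity_map_stack(stack, window_frames=20)

    def test_intensity_scaling_leaves_velocity_maps_unchanged(self):
        rng = np.random.default_rng(3)
        frames = rng.exponential(1.0, size=(60, 6, 6))
        s1 = SpeckleStack(frames, 3000.0, 0.1833, 405.0, 1.0)
        s2 = SpeckleStack(frames * 123.4, 3000.0, 0.1833, 405.0, 1.0)
        v1 = velocity_map_stack(s1)
        v2 = velocity_map_stack(s2)
        assert np.array_equal(v1.valid, v2.valid)
        assert np.allclose(v1.speeds[v1.valid], v2.speeds[v2.valid], rtol=1e-5)
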