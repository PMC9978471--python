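"""Beat-waveform metrics on analytically constructed signals."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ciliaspeckle.beat import (
    BeatWaveform,
    beat_period,
    cbf_fft,
    detect_stroke_peaks,
    roi_waveform,
    stroke_fwhm,
    summarize_beat,
)
from ciliaspeckle.velocimetry import VelocityStack


def spike_train(
    beat_hz=5.0,
    duration=2.0,
    fs=1000.0,
    high_amp=2.0,
    low_amp=1.0,
    high_sigma=0.01,
    low_sigma=0.015,
    low_offset_frac=0.4,
):
    """Two Gaussian spikes per period: a high (power) and a low (recovery) one."""
    t = np.arange(int(round(duration * fs))) / fs
    period = 1.0 / beat_hz
    v = np.zeros_like(t)
    n_beats = int(duration / period) + 1
    for k in range(n_beats):
        t_hi = (k + 0.25) * period
        t_lo = (k + 0.25 + low_offset_frac) * period
        v += high_amp * np.exp(-((t - t_hi) ** 2) / (2 * high_sigma ** 2))
        v += low_amp * np.exp(-((t - t_lo) ** 2) / (2 * low_sigma ** 2))
    return BeatWaveform(times=t, values=v)


class TestRoiWaveform:
    def _vstack(self, speeds, valid=None):
        T = speeds.shape[0]
        if valid is None:
            valid = np.isfinite(speeds)
        return VelocityStack(
            speeds=speeds,
            timestamps=np.arange(T) * 0.01,
            window_frames=20,
            stride_frames=10,
            valid=valid,
        )

    def test_constant_stack_gives_constant_waveform(self):
        vs = self._vstack(np.full((10, 6, 6), 3.0))
        wf = roi_waveform(vs, roi=(1, 5, 1, 5))
        assert wf.values == pytest.approx(np.full(10, 3.0))

    def test_single_pixel_roi_is_identity(self):
        rng = np.random.default_rng(0)
        speeds = rng.uniform(0.1, 1.0, size=(12, 4, 4))
        vs = self._vstack(speeds)
        wf = roi_waveform(vs, roi=(2, 3, 1, 2))
        assert wf.values == pytest.approx(speeds[:, 2, 1])

    def test_masked_pixels_excluded_from_mean(self):
        speeds = np.full((6, 2, 2), 1.0)
        valid = np.ones_like(speeds, dtype=bool)
        speeds[:, 0, 0] = 100.0
        valid[:, 0, 0] = False
        wf = roi_waveform(self._vstack(speeds, valid))
        assert wf.values == pytest.approx(np.ones(6))

    def test_fully_masked_frame_is_nan(self):
        speeds = np.full((6, 2, 2), 1.0)
        valid = np.ones_like(speeds, dtype=bool)
        valid[3] = False
        wf = roi_waveform(self._vstack(speeds, valid))
        assert np.isnan(wf.values[3]) and np.isfinite(wf.values[2])

    def test_empty_or_outside_roi_raises(self):
        vs = self._vstack(np.ones((5, 4, 4)))
        with pytest.raises(ValueError):
            roi_waveform(vs, roi=(2, 2, 0, 4))
        with pytest.raises(ValueError):
            roi_waveform(vs, roi=(0, 5, 0, 4))


class TestCbfFft:
    def test_pure_tone(self):
        t = np.arange(600) / 300.0
        wf = BeatWaveform(times=t, values=np.sin(2 * np.pi * 5.0 * t))
        f, (freqs, amps) = cbf_fft(wf)
        assert f == pytest.approx(5.0, abs=0.05)
        assert len(freqs) == len(amps)

    def test_rectified_sine_doubles_frequency(self):
        # |sin(2 pi 2.5 t)| has its fundamental at 5 Hz
        t = np.arange(600) / 300.0
        wf = BeatWaveform(times=t, values=np.abs(np.sin(2 * np.pi * 2.5 * t)))
        f, _ = cbf_fft(wf)
        assert f == pytest.approx(5.0, abs=0.05)

    def test_amplitude_scale_invariance(self):
        t = np.arange(600) / 300.0
        v = np.sin(2 * np.pi * 4.1 * t)
        f1, _ = cbf_fft(BeatWaveform(times=t, values=v))
        f2, _ = cbf_fft(BeatWaveform(times=t, values=10.0 * v))
        assert f1 == f2

    def test_short_record_raises(self):
        t = np.arange(30) / 30.0  # 1 s record, 0.7 Hz needs >1.43 s
        wf = BeatWaveform(times=t, values=np.sin(2 * np.pi * 5 * t))
        with pytest.raises(ValueError):
            cbf_fft(wf, dc_cutoff_hz=0.7)


class TestStrokePeaks:
    def test_high_low_assignment(self):
        wf = spike_train(high_amp=2.0, low_amp=1.0)
        cycles = detect_stroke_peaks(wf)
        assert len(cycles) >= 8
        for c in cycles:
            assert c.high_peak_value == pytest.approx(2.0, rel=0.05)
            assert c.low_peak_value == pytest.approx(1.0, rel=0.05)
            assert c.high_peak_value >= c.low_peak_value

    def test_sinusoid_high_equals_low(self):
        t = np.arange(2000) / 1000.0
        wf = BeatWaveform(times=t, values=1.5 + np.sin(2 * np.pi * 5 * t))
        cycles = detect_stroke_peaks(wf)
        s = summarize_beat(wf)
        assert s.high_to_low_ratio == pytest.approx(1.0, abs=0.01)

    def test_too_few_peaks_raises(self):
        t = np.arange(2000) / 1000.0
        v = np.exp(-((t - 1.0) ** 2) / (2 * 0.01 ** 2))  # a single spike
        with pytest.raises(ValueError):
            detect_stroke_peaks(BeatWaveform(times=t, values=v))


class TestBeatPeriod:
    def test_exact_intervals(self):
        wf = spike_train(beat_hz=5.0)
        cycles = detect_stroke_peaks(wf)
        mean, sd = beat_period(cycles)
        assert mean == pytest.approx(0.2, abs=2e-3)
        assert sd == pytest.approx(0.0, abs=2e-3)

    def test_hand_arithmetic(self):
        # intervals 0.18, 0.19, 0.20 -> mean 0.190, sample sd 0.010
        class C:
            def __init__(self, t):
                self.high_peak_time = t

        cycles = [C(0.0), C(0.18), C(0.37), C(0.57)]
        mean, sd = beat_period(cycles)
        assert mean == pytest.approx(0.19, abs=1e-12)
        assert sd == pytest.approx(0.01, abs=1e-12)

    def test_single_cycle_raises(self):
        wf = spike_train()
        cycles = detect_stroke_peaks(wf)[:1]
        with pytest.raises(ValueError):
            beat_period(cycles)

    def test_period_and_fft_agree(self):
        # strong power/recovery asymmetry keeps the spectral fundamental
        # dominant over the two-spikes-per-period harmonic
        wf = spike_train(beat_hz=5.0, high_amp=2.0, low_amp=1.0,
                         high_sigma=0.015, low_sigma=0.02, low_offset_frac=0.35)
        f, _ = cbf_fft(wf)
        mean, _ = beat_period(detect_stroke_peaks(wf))
        # one spectral-resolution step of the 2 s record
        assert abs(1.0 / mean - f) < 0.5


class TestFwhm:
    def test_gaussian_closed_form(self):
        # FWHM of a sigma = 0.01 s Gaussian is 2.355 * sigma = 0.02355 s
        fs = 1000.0
        t = np.arange(2000) / fs
        v = np.exp(-((t - 1.0) ** 2) / (2 * 0.01 ** 2))
        wf = BeatWaveform(times=t, values=v)
        assert stroke_fwhm(wf, 1.0) == pytest.approx(2.355 * 0.01, abs=1.0 / fs)

    def test_triangle_geometry(self):
        # triangular spike with base 0.04 s: half height spans 0.020 s
        fs = 1000.0
        t = np.arange(2000) / fs
        v = np.clip(1.0 - np.abs(t - 1.0) / 0.02, 0.0, None)
        wf = BeatWaveform(times=t, values=v)
        assert stroke_fwhm(wf, 1.0) == pytest.approx(0.020, abs=1.5 / fs)

    @given(scale=st.floats(min_value=0.5, max_value=20.0))
    def test_amplitude_invariance(self, scale):
        fs = 1000.0
        t = np.arange(2000) / fs
        v = np.exp(-((t - 1.0) ** 2) / (2 * 0.012 ** 2))
        w1 = stroke_fwhm(BeatWaveform(times=t, values=v), 1.0)
        w2 = stroke_fwhm(BeatWaveform(times=t, values=scale * v), 1.0)
        assert w1 == pytest.approx(w2, rel=1e-9)

    def test_edge_peak_unmeasurable(self):
        t = np.arange(100) / 100.0
        v = np.linspace(0, 1, 100)  # maximum at the record edge
        assert np.isnan(stroke_fwhm(BeatWaveform(times=t, values=v), 0.99))


class TestSummarize:
    @pytest.mark.parametrize(
        "power_fwhm,recovery_fwhm,expected",
        [(0.047, 0.062, 0.76), (0.023, 0.035, 0.66), (0.015, 0.027, 0.55)],
    )
    def test_duration_ratio_from_stroke_fwhms(self, power_fwhm, recovery_fwhm, expected):
        """Waveforms built with the reported stroke FWHMs reproduce the
        reported power/recovery duration ratios (weakened / non-stimulated /
        enhanced regimes)."""
        wf = spike_train(
            beat_hz=2.0,
            duration=4.0,
            fs=2000.0,
            high_amp=0.25,
            low_amp=0.15,
            high_sigma=power_fwhm / 2.355,
            low_sigma=recovery_fwhm / 2.355,
        )
        s = summarize_beat(wf)
        assert s.duration_ratio == pytest.approx(power_fwhm / recovery_fwhm, rel=0.02)
        assert s.duration_ratio == pytest.approx(expected, abs=0.01)

    def test_high_to_low_ratio_is_mean_of_per_cycle_ratios(self):
        wf = spike_train(high_amp=2.0, low_amp=1.0)
        s = summarize_beat(wf)
        assert s.high_to_low_ratio == pytest.approx(2.0, rel=0.05)
        assert s.high_to_low_ratio >= 1.0

    def test_amplitude_scaling_moves_velocities_only(self):
        wf = spike_train(high_amp=0.25, low_amp=0.15)
        s1 = summarize_beat(wf)
        wf2 = BeatWaveform(times=wf.times, values=3.0 * wf.values)
        s2 = summarize_beat(wf2)
        assert s2.cbf_hz == pytest.approx(s1.cbf_hz)
        assert s2.duration_ratio == pytest.approx(s1.duration_ratio, rel=1e-6)
        assert s2.high_to_low_ratio == pytest.approx(s1.high_to_low_ratio, rel=1e-6)
        assert s2.power_velocity_mean == pytest.approx(3 * s1.power_velocity_mean, rel=1e-6)
        assert s2.recovery_velocity_mean == pytest.approx(3 * s1.recovery_velocity_mean, rel=1e-6)
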