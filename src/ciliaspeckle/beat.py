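"""Ciliary beat frequency (CBF) and beat-pattern (CBP) metrics.

A region-of-interest (ROI) average of a velocity stack — or of a
transmission-intensity stack — yields a beat waveform with alternating high
and low peaks: the high peak of each cycle is the fast power stroke, the low
peak the slower recovery stroke, and each high/low pair is one complete
ciliary beat.  From that waveform this module extracts

* the CBF, both as the dominant Fourier frequency (zero-padded magnitude
  spectrum, parabolic sub-bin refinement) and as 1/mean inter-high-peak
  interval,
* stroke durations as the full width at half maximum (FWHM) of each peak,
  measured at half the peak prominence with linear interpolation,
* stroke speeds (peak values), the power/recovery duration ratio, and the
  mean per-cycle high-to-low peak ratio.

ROI boxes are half-open pixel ranges [row0, row1) x [col0, col1), row-major,
origin top-left.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal

from .velocimetry import VelocityStack

__all__ = [
    "BeatWaveform",
    "StrokeCycle",
    "BeatSummary",
    "roi_waveform",
    "detect_stroke_peaks",
    "beat_period",
    "cbf_fft",
    "stroke_fwhm",
    "summarize_beat",
]

Roi = tuple[int, int, int, int]  # row0, row1, col0, col1 (half-open)


@dataclass
class BeatWaveform:
    """Uniformly sampled ROI-averaged time series (velocity or transmission)."""

    times: np.ndarray
    values: np.ndarray
    source: str = "velocity"
    roi: Optional[Roi] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) < 2:
            raise ValueError("a waveform needs at least 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) + self.dt


@dataclass
class StrokeCycle:
    """One complete beat: a power (high) and a recovery (low) peak."""

    high_peak_time: float
    high_peak_value: float
    low_peak_time: float
    low_peak_value: float
    high_fwhm: float  # seconds; NaN when unmeasurable
    low_fwhm: float


@dataclass
class BeatSummary:
    """Aggregated beat metrics for one waveform."""

    cbf_hz: float
    period_mean: float
    period_sd: float
    power_fwhm_mean: float
    power_fwhm_sd: float
    recovery_fwhm_mean: float
    recovery_fwhm_sd: float
    power_velocity_mean: float
    power_velocity_sd: float
    recovery_velocity_mean: float
    recovery_velocity_sd: float
    duration_ratio: float  # mean power FWHM / mean recovery FWHM
    high_to_low_ratio: float  # mean of per-cycle high/low peak-value ratios
    n_cycles: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------


def roi_waveform(
    stack: Union[VelocityStack, np.ndarray],
    roi: Optional[Roi] = None,
    source: Optional[str] = None,
    times: Optional[np.ndarray] = None,
) -> BeatWaveform:
    """Spatially average a stack over an ROI, frame by frame.

    For a :class:`VelocityStack` only valid pixels contribute; a frame whose
    ROI is fully masked yields NaN (flagged missing).  A plain 3-D array is
    treated as a transmission stack and requires ``times``.
    """
    if isinstance(stack, VelocityStack):
        data = stack.speeds
        valid = stack.valid
        t = stack.timestamps
        src = source or "velocity"
    else:
        data = np.asarray(stack, dtype=float)
        if data.ndim != 3:
            raise ValueError("expected a (T, H, W) stack")
        valid = np.isfinite(data)
        if times is None:
            raise ValueError("times are required for a bare array stack")
        t = np.asarray(times, dtype=float)
        src = source or "transmission"

    T, H, W = data.shape
    if roi is None:
        roi = (0, H, 0, W)
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ValueError(f"roi {roi} empty or outside the {H}x{W} frame")
    sub = data[:, r0:r1, c0:c1].reshape(T, -1)
    ok = valid[:, r0:r1, c0:c1].reshape(T, -1)
    counts = ok.sum(axis=1)
    sums = np.where(ok, sub, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, sums / counts, np.nan)
    return BeatWaveform(times=t, values=values, source=src, roi=roi)


def cbf_fft(
    waveform: BeatWaveform,
    dc_cutoff_hz: float = 0.5,
    pad_factor: int = 4,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Dominant beat frequency from the magnitude FFT of the waveform.

    The mean is removed, the record zero-padded ``pad_factor`` times, and the
    largest spectral peak above ``dc_cutoff_hz`` refined by parabolic
    interpolation around the peak bin.  Returns (frequency_hz,
    (frequencies, amplitudes)).

    Raises if the record cannot resolve the cutoff (duration < 1/cutoff) or
    contains missing samples.
    """
    v = waveform.values
    if np.any(~np.isfinite(v)):
        raise ValueError("waveform contains missing samples")
    if dc_cutoff_hz <= 0:
        raise ValueError("dc_cutoff_hz must be positive")
    if waveform.duration < 1.0 / dc_cutoff_hz:
        raise ValueError(
            f"record of {waveform.duration:.3g} s cannot resolve frequencies "
            f"down to the {dc_cutoff_hz} Hz cutoff"
        )
    x = v - v.mean()
    nfft = int(pad_factor) * len(x)
    amp = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, waveform.dt)
    usable = freqs >= dc_cutoff_hz
    if not np.any(usable):
        raise ValueError("no spectral bins above the DC cutoff")
    start = int(np.argmax(usable))
    k = start + int(np.argmax(amp[usable]))
    f = freqs[k]
    if 0 < k < len(amp) - 1:
        a0, a1, a2 = amp[k - 1], amp[k], amp[k + 1]
        denom = a0 - 2 * a1 + a2
        if denom != 0:
            delta = 0.5 * (a0 - a2) / denom
            f = freqs[k] + np.clip(delta, -1, 1) * (freqs[1] - freqs[0])
    return float(f), (freqs, amp)


def detect_stroke_peaks(
    waveform: BeatWaveform,
    prominence_frac: float = 0.25,
    min_separation_frac: float = 0.25,
    dc_cutoff_hz: float = 0.5,
) -> list[StrokeCycle]:
    """Find alternating high/low peaks and pair them into beat cycles.

    Local maxima are kept when their prominence exceeds ``prominence_frac``
    of the waveform's robust range (95th - 5th percentile) and they are
    separated by at least ``min_separation_frac`` of the dominant period
    (from an initial FFT pass).  Consecutive peaks are paired; within a pair
    the larger is the power (high) peak, the smaller the recovery (low) peak.

    Raises when fewer than two qualifying peaks exist.
    """
    v = waveform.values
    if np.any(~np.isfinite(v)):
        raise ValueError("waveform contains missing samples")
    f0, _ = cbf_fft(waveform, dc_cutoff_hz=dc_cutoff_hz)
    period_samples = waveform.sampling_rate / f0
    distance = max(1, int(round(min_separation_frac * period_samples)))
    lo, hi = np.percentile(v, [5.0, 95.0])
    prominence = prominence_frac * (hi - lo)
    peaks, _ = signal.find_peaks(v, prominence=prominence, distance=distance)
    if len(peaks) < 2:
        raise ValueError("fewer than 2 qualifying peaks: no beat cycle detected")

    # classify the waveform by the structure of its detected peak values:
    # * uniform (one equal peak per period, e.g. a sinusoid) and spiky
    #   (distinct power and recovery peaks) records pair consecutive peaks;
    # * plateau records (rectangular speed alternation) raise prominent
    #   peaks only on the power level, so recovery peaks are recovered from
    #   the samples between consecutive power peaks.
    pv = peaks
    vals = v[pv]
    sorted_vals = np.sort(vals)
    gaps = np.diff(sorted_vals)
    split_at = int(np.argmax(gaps)) + 1 if len(gaps) else 0
    uniform = (sorted_vals[-1] - sorted_vals[0]) < prominence if len(vals) else True
    spiky = False
    if not uniform:
        threshold = 0.5 * (sorted_vals[split_at - 1] + sorted_vals[split_at])
        classes = vals > threshold
        n_high_cls = int(classes.sum())
        n_low_cls = len(classes) - n_high_cls
        balanced = min(n_low_cls, n_high_cls) >= 0.5 * max(n_low_cls, n_high_cls)
        # true two-peaks-per-beat waveforms alternate high/low strictly and
        # raise about two qualifying peaks per dominant period
        alternation = float(np.mean(classes[:-1] != classes[1:])) if len(classes) > 1 else 0.0
        n_periods = waveform.duration * f0
        spiky = balanced and alternation >= 0.75 and len(pv) <= 2.4 * n_periods

    if uniform or spiky:
        pairs = [(pv[i], pv[i + 1]) for i in range(0, len(pv) - 1, 2)]
    else:
        # plateau regime: prominent peaks all sit on the power level; find
        # one power peak per period, then place each recovery peak at the
        # highest sample between power peaks that is clearly off the
        # power plateau
        one_per_period = max(distance, int(round(0.55 * period_samples)))
        highs, _ = signal.find_peaks(v, prominence=prominence, distance=one_per_period)
        high_level = float(np.median(v[highs])) if len(highs) else hi
        cutoff = 0.5 * (high_level + lo)
        highs = highs[v[highs] > cutoff]  # drop recovery-level noise peaks
        pairs = []
        for a, b in zip(highs[:-1], highs[1:]):
            seg = np.arange(a + 1, b)
            seg = seg[v[seg] <= cutoff]
            if len(seg) == 0:
                continue
            pairs.append((a, seg[np.argmax(v[seg])]))
    if not pairs:
        raise ValueError("no complete high/low cycle detected")

    all_idx = np.array([i for pair in pairs for i in pair])
    with warnings.catch_warnings():
        # plateau-regime recovery points need not be strict local maxima;
        # their widths come out 0 and are flagged unmeasurable below
        warnings.simplefilter("ignore")
        widths = signal.peak_widths(v, all_idx, rel_height=0.5)[0] * waveform.dt
    edge = (all_idx <= 0) | (all_idx >= len(v) - 1)
    widths = np.where(edge | (widths <= 0), np.nan, widths)
    width_of = dict(zip(all_idx.tolist(), widths.tolist()))

    cycles: list[StrokeCycle] = []
    for pa, pb in pairs:
        wa, wb = width_of[pa], width_of[pb]
        if v[pa] >= v[pb]:
            hi_p, lo_p, hi_w, lo_w = pa, pb, wa, wb
        else:
            hi_p, lo_p, hi_w, lo_w = pb, pa, wb, wa
        cycles.append(
            StrokeCycle(
                high_peak_time=float(waveform.times[hi_p]),
                high_peak_value=float(v[hi_p]),
                low_peak_time=float(waveform.times[lo_p]),
                low_peak_value=float(v[lo_p]),
                high_fwhm=float(hi_w),
                low_fwhm=float(lo_w),
            )
        )
    return cycles


def beat_period(cycles: Sequence[StrokeCycle]) -> tuple[float, float]:
    """Mean and sample SD of the intervals between consecutive high peaks."""
    if len(cycles) < 2:
        raise ValueError("at least 2 cycles are required to estimate a period")
    highs = np.sort([c.high_peak_time for c in cycles])
    intervals = np.diff(highs)
    sd = float(np.std(intervals, ddof=1)) if len(intervals) > 1 else 0.0
    return float(np.mean(intervals)), sd


def stroke_fwhm(waveform: BeatWaveform, peak_time: float) -> float:
    """FWHM (seconds) of the peak nearest ``peak_time``.

    Width at half the peak prominence (half height measured from the local
    baseline between surrounding troughs), linearly interpolated between
    samples.  Returns NaN when the half level is never crossed on either
    side (flagged unmeasurable).
    """
    v = waveform.values
    idx = int(np.argmin(np.abs(waveform.times - peak_time)))
    # walk to the nearest local maximum so callers may pass approximate times
    while 0 < idx < len(v) - 1 and (v[idx + 1] > v[idx] or v[idx - 1] > v[idx]):
        idx += 1 if v[idx + 1] > v[idx] else -1
    if idx <= 0 or idx >= len(v) - 1:
        return float("nan")
    try:
        width = signal.peak_widths(v, [idx], rel_height=0.5)[0][0]
    except ValueError:
        return float("nan")
    return float(width * waveform.dt)


def summarize_beat(
    waveform: BeatWaveform,
    prominence_frac: float = 0.25,
    min_separation_frac: float = 0.25,
    dc_cutoff_hz: float = 0.5,
) -> BeatSummary:
    """Full beat-pattern summary of one waveform.

    ``duration_ratio`` is mean power FWHM / mean recovery FWHM;
    ``high_to_low_ratio`` is the mean over cycles of the per-cycle
    high/low peak-value ratio.  FWHM-based stroke metrics are meaningful for
    velocity waveforms; for transmission input they describe intensity peaks.
    """
    cycles = detect_stroke_peaks(
        waveform,
        prominence_frac=prominence_frac,
        min_separation_frac=min_separation_frac,
        dc_cutoff_hz=dc_cutoff_hz,
    )
    cbf, _ = cbf_fft(waveform, dc_cutoff_hz=dc_cutoff_hz)
    if len(cycles) >= 2:
        period_mean, period_sd = beat_period(cycles)
    else:
        period_mean, period_sd = float("nan"), float("nan")

    hi_v = np.array([c.high_peak_value for c in cycles])
    lo_v = np.array([c.low_peak_value for c in cycles])
    hi_w = np.array([c.high_fwhm for c in cycles])
    lo_w = np.array([c.low_fwhm for c in cycles])

    def _msd(a: np.ndarray) -> tuple[float, float]:
        a = a[np.isfinite(a)]
        if len(a) == 0:
            return float("nan"), float("nan")
        sd = float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
        return float(np.mean(a)), sd

    pw_m, pw_s = _msd(hi_w)
    rw_m, rw_s = _msd(lo_w)
    pv_m, pv_s = _msd(hi_v)
    rv_m, rv_s = _msd(lo_v)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = hi_v / lo_v
    ratios = ratios[np.isfinite(ratios)]
    return BeatSummary(
        cbf_hz=cbf,
        period_mean=period_mean,
        period_sd=period_sd,
        power_fwhm_mean=pw_m,
        power_fwhm_sd=pw_s,
        recovery_fwhm_mean=rw_m,
        recovery_fwhm_sd=rw_s,
        power_velocity_mean=pv_m,
        power_velocity_sd=pv_s,
        recovery_velocity_mean=rv_m,
        recovery_velocity_sd=rv_s,
        duration_ratio=pw_m / rw_m if rw_m and np.isfinite(rw_m) and rw_m > 0 else float("nan"),
        high_to_low_ratio=float(np.mean(ratios)) if len(ratios) else float("nan"),
        n_cycles=len(cycles),
    )
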