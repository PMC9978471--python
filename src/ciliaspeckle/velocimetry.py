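"""Temporal speckle autocorrelation velocimetry.

Raw dynamic-speckle stacks are converted into absolute speed maps in three
steps, applied per pixel inside a moving time window:

1. estimate the normalized intensity autocorrelation
   g2(tau_k) = <I(t) I(t+tau_k)> / <I>^2  for lags tau_k = k / frame_rate,
2. fit the Siegert model
   g2(tau) = 1 + beta * exp(-2 (tau/tau_c)^n),
   where beta is the setup-dependent coherence factor and tau_c the speckle
   decorrelation time (n = 1 for single scattering),
3. convert the decorrelation time to an absolute speed,
   v = lambda / (pi * NA * tau_c).

The decorrelation time is inversely proportional to the scatterer speed, so
fast motion (a ciliary power stroke) shows up as a short tau_c and a high
speed.  Pixels whose correlogram carries no measurable decay, or whose fit
runs into a parameter bound, are masked rather than zeroed so that spatial
averages downstream are not biased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "SpeckleStack",
    "Correlogram",
    "CorrelogramFit",
    "VelocityStack",
    "FIT_OK",
    "FIT_NO_DECAY",
    "FIT_TAU_BOUND",
    "FIT_BETA_FLOOR",
    "FIT_RSS_CAP",
    "estimate_g2",
    "fit_siegert",
    "tau_to_velocity",
    "velocity_map_stack",
]

# Fit status codes (stored per pixel per window).
FIT_OK = 0
FIT_NO_DECAY = 1  # g2(first lag) - 1 below the noise floor
FIT_TAU_BOUND = 2  # tau_c pinned at a configured bound
FIT_BETA_FLOOR = 3  # fitted beta below the noise floor
FIT_RSS_CAP = 4  # residual sum of squares above the configured cap

FIT_REASONS = {
    FIT_OK: "ok",
    FIT_NO_DECAY: "no_decay",
    FIT_TAU_BOUND: "tau_at_bound",
    FIT_BETA_FLOOR: "beta_below_floor",
    FIT_RSS_CAP: "rss_above_cap",
}


@dataclass
class SpeckleStack:
    """Time-ordered speckle frames plus the acquisition metadata needed to
    turn decorrelation times into absolute speeds.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative intensities, acquisition order.
    frame_rate : float
        Frames per second.
    effective_pixel_size : float
        Object-space pixel pitch in micrometres (camera pixel / magnification).
    wavelength : float
        Illumination wavelength in nanometres.
    detection_na : float
        Numerical aperture of the detection objective.
    """

    frames: np.ndarray
    frame_rate: float
    effective_pixel_size: float
    wavelength: float
    detection_na: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (T, H, W) array with T >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.detection_na <= 1.5:
            raise ValueError("detection_na must lie in (0, 1.5]")
        if self.effective_pixel_size <= 0:
            raise ValueError("effective_pixel_size must be positive")
        if np.nanmin(self.frames) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Record duration in seconds (frame count / frame rate)."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class Correlogram:
    """Estimated g2(tau) at positive integer-frame lags.

    ``n_samples_per_lag`` counts the intensity pairs that entered each lag and
    is used as the fit weight.  ``flat`` marks a constant input series, for
    which g2 is identically 1 and carries no motion information.
    """

    lags: np.ndarray
    g2_values: np.ndarray
    n_samples_per_lag: np.ndarray
    flat: bool = False

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g2_values = np.asarray(self.g2_values, dtype=float)
        self.n_samples_per_lag = np.asarray(self.n_samples_per_lag)
        if self.lags.ndim != 1 or len(self.lags) != len(self.g2_values):
            raise ValueError("lags and g2_values must be 1-D and equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.g2_values < 0):
            raise ValueError("g2 values must be non-negative")


@dataclass
class CorrelogramFit:
    """Result of a Siegert-model fit on one correlogram."""

    beta: float
    tau_c: float
    n_exponent: float
    rss: float
    valid: bool
    reason: str = "ok"


@dataclass
class VelocityStack:
    """Time series of per-pixel speed maps (mm/s) from moving-window fits.

    ``speeds`` holds NaN where the fit was invalid; ``valid`` is the companion
    mask.  Timestamps are nominal window-centre times on a uniform grid.
    """

    speeds: np.ndarray
    timestamps: np.ndarray
    window_frames: int
    stride_frames: int
    valid: np.ndarray
    frame_rate: float = 0.0
    effective_pixel_size: float = 0.0

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.speeds.shape != self.valid.shape:
            raise ValueError("speeds and valid mask must share a shape")
        if len(self.timestamps) != self.speeds.shape[0]:
            raise ValueError("one timestamp per window is required")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.speeds[self.valid] < 0):
                raise ValueError("valid speeds must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.speeds.shape[0]


# ---------------------------------------------------------------------------
# g2 estimation
# ---------------------------------------------------------------------------


def _g2_block(block: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """g2 for a (T, P) block of P pixel traces; returns (g2 (L, P), counts (L,))."""
    block = np.asarray(block, dtype=np.float64)
    T = block.shape[0]
    mean = block.mean(axis=0)
    denom = mean * mean
    g2 = np.empty((max_lag, block.shape[1]))
    counts = np.empty(max_lag, dtype=np.int64)
    for k in range(1, max_lag + 1):
        prod = block[:-k] * block[k:]
        counts[k - 1] = T - k
        g2[k - 1] = prod.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = g2 / denom
    return g2, counts


def estimate_g2(intensities: np.ndarray, max_lag_frames: int, frame_rate: float = 1.0) -> Correlogram:
    """Estimate the normalized intensity autocorrelation of one pixel trace.

    g2(tau_k) = mean_t[ I(t) I(t + k) ] / mean[I]^2 for k = 1..max_lag_frames,
    using every valid pair inside the window.

    Parameters
    ----------
    intensities : 1-D array
        Intensity series of a single pixel inside one time window.
    max_lag_frames : int
        Largest lag, in frames.  Must satisfy max_lag_frames <= len - 2.
    frame_rate : float
        Converts integer-frame lags into seconds (first lag = 1/frame_rate).

    Raises
    ------
    ValueError
        If the window is too short or the series is identically zero
        (the normalization is undefined).
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("intensities must be 1-D; use velocity_map_stack for images")
    if max_lag_frames < 1 or max_lag_frames > len(x) - 2:
        raise ValueError(
            f"max_lag_frames must be in [1, {len(x) - 2}] for a window of {len(x)} frames"
        )
    if np.all(x == 0):
        raise ValueError("all-zero window: g2 normalization undefined")
    flat = bool(np.all(x == x[0]))
    g2, counts = _g2_block(x[:, None], max_lag_frames)
    g2 = g2[:, 0]
    if flat:
        g2 = np.ones_like(g2)
    lags = np.arange(1, max_lag_frames + 1) / frame_rate
    return Correlogram(lags=lags, g2_values=g2, n_samples_per_lag=counts, flat=flat)


# ---------------------------------------------------------------------------
# Siegert fit
# ---------------------------------------------------------------------------


def _fit_siegert_batch(
    lags: np.ndarray,
    g2: np.ndarray,
    weights: np.ndarray,
    n_exponent: float = 1.0,
    noise_floor: float = 0.05,
    tau_bounds: Optional[tuple[float, float]] = None,
    rss_cap: Optional[float] = None,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized weighted fit of g2 = 1 + beta exp(-2 (tau/tau_c)^n).

    Damped Gauss-Newton on (beta, log tau_c) for P correlograms at once,
    seeded by a weighted log-linear regression of ln(g2 - 1) on tau^n.
    beta is constrained to (0, 1].

    Parameters are shared across columns; ``g2`` has shape (L, P).
    Returns (beta, tau_c, rss, status_code) each of shape (P,).
    """
    lags = np.asarray(lags, dtype=np.float64)
    g2 = np.atleast_2d(np.asarray(g2, dtype=np.float64))
    if g2.shape[0] != len(lags):
        raise ValueError("g2 must have one row per lag")
    L, P = g2.shape
    if L < 3:
        raise ValueError("at least 3 lag points are required to fit the Siegert model")
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim == 1:
        w = w[:, None]
    w = np.broadcast_to(w, g2.shape)

    if tau_bounds is None:
        tau_bounds = (0.1 * lags[0], 100.0 * lags[-1])
    tau_lo, tau_hi = tau_bounds
    p_lo, p_hi = np.log(tau_lo), np.log(tau_hi)
    n = float(n_exponent)
    if n <= 0:
        raise ValueError("n_exponent must be positive")

    y = g2 - 1.0
    # --- log-linear initializer on points with measurable decay ---
    pos = y > 1e-12
    wl = w * np.square(y) * pos  # y^2 weighting approximates LSQ in linear space
    ly = np.where(pos, np.log(np.clip(y, 1e-300, None)), 0.0)
    xn = (lags ** n)[:, None]
    s0 = wl.sum(axis=0)
    s1 = (wl * xn).sum(axis=0)
    s2 = (wl * xn * xn).sum(axis=0)
    sy = (wl * ly).sum(axis=0)
    sxy = (wl * xn * ly).sum(axis=0)
    det = s0 * s2 - s1 * s1
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (s0 * sxy - s1 * sy) / det
        intercept = (sy * s2 - s1 * sxy) / det
    ok_init = (pos.sum(axis=0) >= 3) & np.isfinite(slope) & (slope < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau0 = np.where(ok_init, (-2.0 / np.where(slope < 0, slope, -1.0)) ** (1.0 / n), np.nan)
    tau0 = np.where(ok_init, tau0, np.sqrt(lags[0] * lags[-1]))
    beta0 = np.where(ok_init, np.exp(np.clip(intercept, -50, 0.0)), np.clip(y[0], 1e-3, 1.0))

    b = np.clip(beta0, 1e-6, 1.0)
    p = np.clip(np.log(tau0), p_lo, p_hi)
    lam = np.full(P, 1e-3)

    def model_rss(bv, pv):
        u = lags[:, None] * np.exp(-pv)[None, :]
        un = u ** n
        e = np.exp(-2.0 * un)
        r = y - bv[None, :] * e
        return e, un, r, (w * r * r).sum(axis=0)

    e, un, r, rss = model_rss(b, p)
    for _ in range(max_iter):
        jb = e
        jp = b[None, :] * e * (2.0 * n * un)
        a11 = (w * jb * jb).sum(axis=0) * (1.0 + lam)
        a22 = (w * jp * jp).sum(axis=0) * (1.0 + lam)
        a12 = (w * jb * jp).sum(axis=0)
        g1v = (w * jb * r).sum(axis=0)
        g2v = (w * jp * r).sum(axis=0)
        det = a11 * a22 - a12 * a12
        safe = np.abs(det) > 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            db = np.where(safe, (a22 * g1v - a12 * g2v) / det, 0.0)
            dp = np.where(safe, (a11 * g2v - a12 * g1v) / det, 0.0)
        dp = np.clip(dp, -1.5, 1.5)
        b_new = np.clip(b + db, 1e-6, 1.0)
        p_new = np.clip(p + dp, p_lo, p_hi)
        e_n, un_n, r_n, rss_new = model_rss(b_new, p_new)
        better = rss_new <= rss + 1e-18
        b = np.where(better, b_new, b)
        p = np.where(better, p_new, p)
        e = np.where(better[None, :], e_n, e)
        un = np.where(better[None, :], un_n, un)
        r = np.where(better[None, :], r_n, r)
        rss = np.where(better, rss_new, rss)
        lam = np.clip(np.where(better, lam * 0.4, lam * 5.0), 1e-12, 1e6)
        if np.all(np.maximum(np.abs(db), np.abs(dp)) < 1e-12):
            break

    tau = np.exp(p)
    code = np.zeros(P, dtype=np.int8)
    rel = 1e-6
    at_bound = (tau <= tau_lo * (1 + rel)) | (tau >= tau_hi * (1 - rel))
    code[at_bound] = FIT_TAU_BOUND
    code[b < noise_floor] = FIT_BETA_FLOOR
    if rss_cap is not None:
        code[rss > rss_cap] = FIT_RSS_CAP
    code[y[0] < noise_floor] = FIT_NO_DECAY
    # raw (unweighted) residual sum of squares, as reported per fit
    rss_raw = (r * r).sum(axis=0)
    return b, tau, rss_raw, code


def _window_mean_inflation(r: np.ndarray, T: int) -> np.ndarray:
    """S(r) with E[sample-mean^2] = mu^2 (1 + beta S / T^2) for an
    exponentially correlated series of length T (correlation ratio r per
    frame): S = T + 2 sum_{m=1}^{T-1} (T - m) r^m."""
    m = np.arange(1, T)
    rm = r[None, :] ** m[:, None]
    return T + 2.0 * ((T - m)[:, None] * rm).sum(axis=0)


def _fit_tau_batch(
    lags: np.ndarray,
    g2: np.ndarray,
    contrast_sq: np.ndarray,
    window_frames: int,
    weights: np.ndarray,
    noise_floor: float = 0.05,
    tau_bounds: Optional[tuple[float, float]] = None,
    max_iter: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit tau_c only, anchoring beta at the measured squared contrast and
    modelling the finite-window estimator bias.

    With short correlograms the joint (beta, tau_c) problem is a shallow
    ridge: many (small beta, long tau) pairs fit a fast decay equally well,
    which biases batch estimates.  beta is however directly measurable as
    the zero-lag point of the model, g2(0) - 1 = Var(I)/mean(I)^2 (the
    squared temporal speckle contrast), so anchoring it and solving the
    1-parameter problem removes the degeneracy.

    Both the correlogram and the measured contrast are normalized by the
    window sample mean, whose fluctuations are correlated with the signal.
    To first order, for an exponentially correlated series with per-frame
    ratio r = exp(-2 dt / tau_c) and S = S(r):

        E[g2_hat(k)] = (1 + beta r^k) / (1 + beta S / T^2)
        E[contrast^2_hat] = beta (1 - S / T^2) / (1 + beta S / T^2)

    so beta is recovered from the measured contrast and the model compared
    with the raw (biased) correlogram directly.  For long windows S/T^2 -> 0
    and the correction vanishes.

    Returns (tau_c, beta, rss, status_code), each (P,).
    """
    lags = np.asarray(lags, dtype=np.float64)
    g2 = np.atleast_2d(np.asarray(g2, dtype=np.float64))
    L, P = g2.shape
    T = int(window_frames)
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim == 1:
        w = w[:, None]
    w = np.broadcast_to(w, g2.shape)
    bhat = np.clip(np.asarray(contrast_sq, dtype=np.float64), 1e-6, 1.5)
    if tau_bounds is None:
        tau_bounds = (0.1 * lags[0], 100.0 * lags[-1])
    p_lo, p_hi = np.log(tau_bounds[0]), np.log(tau_bounds[1])
    dt = lags[0]
    k_exp = (lags / dt).round()[:, None]

    y1 = np.clip(g2[0] - 1.0, 1e-6, None)
    r0 = np.clip(y1 / bhat, 1e-6, 0.999)
    p = np.clip(np.log(-2.0 * dt / np.log(r0)), p_lo, p_hi)
    lam = np.full(P, 1e-3)

    def model(pv):
        r = np.exp(-2.0 * dt / np.exp(pv))
        s_frac = _window_mean_inflation(r, T) / (T * T)
        denom_b = np.clip((1.0 - s_frac) - bhat * s_frac, 1e-3, None)
        beta = np.clip(bhat / denom_b, 1e-6, 1.2)
        g_model = (1.0 + beta[None, :] * r[None, :] ** k_exp) / (1.0 + beta * s_frac)[None, :]
        res = g2 - g_model
        return beta, res, (w * res * res).sum(axis=0)

    beta, res, rss = model(p)
    h = 1e-5
    for _ in range(max_iter):
        _, res_h, _ = model(p + h)
        jac = (res - res_h) / h  # d model / dp
        a = (w * jac * jac).sum(axis=0) * (1.0 + lam)
        g = (w * jac * res).sum(axis=0)
        dp = np.clip(np.where(a > 1e-300, g / a, 0.0), -1.5, 1.5)
        p_new = np.clip(p + dp, p_lo, p_hi)
        beta_n, res_n, rss_new = model(p_new)
        better = rss_new <= rss + 1e-18
        p = np.where(better, p_new, p)
        beta = np.where(better, beta_n, beta)
        res = np.where(better[None, :], res_n, res)
        rss = np.where(better, rss_new, rss)
        lam = np.clip(np.where(better, lam * 0.4, lam * 5.0), 1e-12, 1e6)
        if np.all(np.abs(dp) < 1e-10):
            break

    tau = np.exp(p)
    code = np.zeros(P, dtype=np.int8)
    rel = 1e-6
    code[(tau <= tau_bounds[0] * (1 + rel)) | (tau >= tau_bounds[1] * (1 - rel))] = FIT_TAU_BOUND
    code[bhat < noise_floor] = FIT_BETA_FLOOR
    code[g2[0] - 1.0 < noise_floor] = FIT_NO_DECAY
    return tau, beta, (res * res).sum(axis=0), code


def fit_siegert(
    correlogram: Correlogram,
    n_exponent: float = 1.0,
    noise_floor: float = 0.05,
    tau_bounds: Optional[tuple[float, float]] = None,
    rss_cap: Optional[float] = None,
) -> CorrelogramFit:
    """Fit the Siegert model to one correlogram.

    Minimizes the squared error of g2(tau) = 1 + beta exp(-2 (tau/tau_c)^n)
    weighted by the pair count per lag.  A fit is invalid (not an exception)
    when the first-lag decay is below ``noise_floor``, when tau_c pins at a
    bound, or when the residual exceeds ``rss_cap``.
    """
    if len(correlogram.lags) < 3:
        raise ValueError("at least 3 lag points are required")
    if correlogram.flat or np.all(correlogram.g2_values <= 1.0):
        return CorrelogramFit(
            beta=0.0, tau_c=np.inf, n_exponent=n_exponent, rss=0.0,
            valid=False, reason=FIT_REASONS[FIT_NO_DECAY],
        )
    b, tau, rss, code = _fit_siegert_batch(
        correlogram.lags,
        correlogram.g2_values[:, None],
        np.asarray(correlogram.n_samples_per_lag, dtype=float),
        n_exponent=n_exponent,
        noise_floor=noise_floor,
        tau_bounds=tau_bounds,
        rss_cap=rss_cap,
    )
    c = int(code[0])
    return CorrelogramFit(
        beta=float(b[0]),
        tau_c=float(tau[0]),
        n_exponent=n_exponent,
        rss=float(rss[0]),
        valid=c == FIT_OK,
        reason=FIT_REASONS[c],
    )


def tau_to_velocity(tau_c, wavelength: float, detection_na: float):
    """Convert a decorrelation time to an absolute speed, v = lambda/(pi NA tau_c).

    Parameters
    ----------
    tau_c : float or ndarray
        Decorrelation time in seconds (must be positive).
    wavelength : float
        Wavelength in nanometres.
    detection_na : float
        Detection numerical aperture.

    Returns
    -------
    Speed in mm/s (same shape as ``tau_c``).
    """
    if wavelength <= 0 or detection_na <= 0:
        raise ValueError("wavelength and detection_na must be positive")
    tau = np.asarray(tau_c, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_c must be positive")
    lam_mm = wavelength * 1e-6  # nm -> mm
    v = lam_mm / (np.pi * detection_na * tau)
    return float(v) if np.isscalar(tau_c) else v


# ---------------------------------------------------------------------------
# moving-window velocity maps
# ---------------------------------------------------------------------------


def window_start_indices(
    n_frames: int, window_frames: int, stride_frames: int, max_lag_frames: int
) -> list[int]:
    """Start indices of the moving windows.

    Every multiple of the stride below ``n_frames`` starts a window; final
    windows are truncated to the available frames.  A truncated window is kept
    as long as it still supports at least 3 lags (length >= 5); its lag count
    is capped at length - 2.  With 3000 frames, window 20 and stride 10 this
    yields start indices 0, 10, ..., 2990 — i.e. 300 windows.
    """
    if window_frames < 5:
        raise ValueError("window_frames must be at least 5 (>= 3 lags + 2)")
    if stride_frames < 1:
        raise ValueError("stride_frames must be >= 1")
    starts = []
    for s in range(0, n_frames, stride_frames):
        win_len = min(window_frames, n_frames - s)
        if win_len >= 5 and min(max_lag_frames, win_len - 2) >= 3:
            starts.append(s)
    return starts


def velocity_map_stack(
    stack: SpeckleStack,
    window_frames: int = 20,
    stride_frames: int = 10,
    max_lag_frames: Optional[int] = None,
    n_exponent: float = 1.0,
    noise_floor: float = 0.05,
    rss_cap: Optional[float] = None,
    beta_mode: str = "contrast",
) -> VelocityStack:
    """Per-pixel moving-window autocorrelation velocimetry over a full stack.

    For each window start (multiples of the stride) and each pixel:
    estimate g2, fit the Siegert model, convert tau_c to mm/s.  Invalid fits
    are masked (NaN speed, valid=False).  Timestamps are nominal window
    centres, (start + (window_frames - 1)/2) / frame_rate, so the output grid
    is uniform.

    ``beta_mode`` selects the fit strategy: "contrast" (default) anchors the
    coherence factor at the measured squared temporal speckle contrast of the
    window, Var(I)/mean(I)^2, and fits tau_c alone; "free" fits (beta, tau_c)
    jointly (requires n_exponent support and is noisier on short windows).

    ``max_lag_frames`` defaults to window_frames // 2 (10 lags for the default
    20-frame window, keeping >= 10 pair samples per lag).
    """
    if beta_mode not in ("contrast", "free"):
        raise ValueError("beta_mode must be 'contrast' or 'free'")
    if max_lag_frames is None:
        max_lag_frames = window_frames // 2
    if max_lag_frames < 3:
        raise ValueError("max_lag_frames must be >= 3")
    T, H, W = stack.frames.shape
    if T < window_frames:
        raise ValueError("stack shorter than one window")
    starts = window_start_indices(T, window_frames, stride_frames, max_lag_frames)
    n_win = len(starts)
    P = H * W
    speeds = np.full((n_win, H, W), np.nan)
    valid = np.zeros((n_win, H, W), dtype=bool)
    fps = stack.frame_rate
    window_duration = window_frames / fps
    tau_bounds = (0.1 / fps, 100.0 * window_duration)

    frames_flat = stack.frames.reshape(T, P).astype(np.float64)
    for i, s in enumerate(starts):
        win_len = min(window_frames, T - s)
        L = min(max_lag_frames, win_len - 2)
        block = frames_flat[s : s + win_len]
        mean = block.mean(axis=0)
        nonzero = mean > 0
        g2, counts = _g2_block(block, L)
        lags = np.arange(1, L + 1) / fps
        if beta_mode == "contrast":
            with np.errstate(divide="ignore", invalid="ignore"):
                contrast_sq = np.where(
                    nonzero, block.var(axis=0) / np.where(nonzero, mean, 1.0) ** 2, 0.0
                )
            tau, _, rss, code = _fit_tau_batch(
                lags,
                g2,
                contrast_sq,
                win_len,
                counts.astype(float),
                noise_floor=noise_floor,
                tau_bounds=tau_bounds,
            )
        else:
            b, tau, rss, code = _fit_siegert_batch(
                lags,
                g2,
                counts.astype(float),
                n_exponent=n_exponent,
                noise_floor=noise_floor,
                tau_bounds=tau_bounds,
                rss_cap=rss_cap,
            )
        ok = (code == FIT_OK) & nonzero & np.isfinite(tau)
        v = np.full(P, np.nan)
        v[ok] = tau_to_velocity(tau[ok], stack.wavelength, stack.detection_na)
        speeds[i] = v.reshape(H, W)
        valid[i] = ok.reshape(H, W)

    timestamps = (np.asarray(starts) + (window_frames - 1) / 2.0) / fps
    return VelocityStack(
        speeds=speeds,
        timestamps=timestamps,
        window_frames=window_frames,
        stride_frames=stride_frames,
        valid=valid,
        frame_rate=fps,
        effective_pixel_size=stack.effective_pixel_size,
    )
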