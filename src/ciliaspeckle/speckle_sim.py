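"""Synthetic dynamic-speckle generation with programmable cilia-like motion.

The scene is a 2-D field of discrete point scatterers with random complex
scattering amplitudes.  A frame is the squared magnitude of the coherent sum
of their contributions imaged through a Gaussian coherent point-spread
function (PSF), which for dense fields produces fully developed speckle
(negative-exponential intensity statistics, contrast sigma/mu = 1).

Motion enters in two ways:

* the scatterer positions advance each frame interval according to a
  :class:`MotionProgram` (static, uniform translation, Brownian, or an
  asymmetric power/recovery beating cycle), translating the speckle
  envelope, and
* each scatterer optionally carries a scattering-wavevector offset q_j whose
  dot product with the accumulated displacement advances the phase of its
  contribution.  The q_j are drawn from an isotropic 2-D Cauchy distribution
  with scale pi*NA/lambda, which makes the ensemble field correlation of
  directed motion decay exactly exponentially,

      g1(tau) = exp(-pi * NA * v * tau / lambda),

  i.e. the single-scattering regime in which the downstream Siegert fit
  (n = 1) and the speed conversion v = lambda/(pi NA tau_c) are exact.

Disabling ``dephasing`` yields rigid translation of the speckle pattern —
frames are exact cyclic shifts of each other when the per-frame displacement
is an integer number of pixels — which is the right fixture when the
displacement signal itself (PIV) is under test rather than speckle
decorrelation.

Scatterers live on a torus: anything translating out of the field re-enters
on the opposite side, so density and speckle statistics are stationary over
arbitrarily long stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .velocimetry import SpeckleStack

__all__ = [
    "ScattererField",
    "MotionProgram",
    "SimConfig",
    "GroundTruthTrace",
    "render_speckle_frame",
    "simulate_stack",
]


@dataclass(frozen=True)
class ScattererField:
    """Random point scatterers inside a rectangular field.

    positions : (N, 2) array of (row, col) coordinates in micrometres
    amplitudes : (N,) complex scattering strengths (non-zero)
    extent : (height_um, width_um) of the field
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.float64))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=np.complex128))
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if len(self.positions) == 0:
            raise ValueError("scatterer field must contain at least one scatterer")
        if len(self.amplitudes) != len(self.positions):
            raise ValueError("one amplitude per scatterer is required")
        if np.any(np.abs(self.amplitudes) == 0):
            raise ValueError("amplitudes must be non-zero")
        h, w = self.extent
        if h <= 0 or w <= 0:
            raise ValueError("field extent must be positive")
        if np.any(self.positions < 0) or np.any(self.positions >= np.array([h, w])):
            raise ValueError("positions must lie inside the field extent")

    @property
    def density(self) -> float:
        """Scatterers per square micrometre."""
        return len(self.positions) / (self.extent[0] * self.extent[1])

    @classmethod
    def random(
        cls,
        extent: tuple[float, float],
        density: float,
        rng: np.random.Generator,
    ) -> "ScattererField":
        """Uniform random positions with circular-Gaussian complex amplitudes."""
        if density <= 0:
            raise ValueError("density must be positive")
        h, w = extent
        n = max(1, int(round(density * h * w)))
        positions = rng.uniform(0.0, [h, w], size=(n, 2))
        amplitudes = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / math.sqrt(2.0)
        # a vanishing amplitude has probability zero; regenerate defensively
        bad = np.abs(amplitudes) == 0
        if np.any(bad):
            amplitudes[bad] = 1.0 / math.sqrt(2.0)
        return cls(positions=positions, amplitudes=amplitudes, extent=extent)


@dataclass(frozen=True)
class MotionProgram:
    """Kinematic program applied identically to every scatterer in a patch.

    ``beating`` alternates a power stroke (fraction ``power_fraction`` of the
    period, speed ``speed_power`` along ``direction_power``) with a recovery
    stroke covering the rest of the period at ``speed_recovery`` along the
    reversed direction.  Speeds are micrometres per second.
    """

    kind: str
    speed_power: float = 0.0
    speed_recovery: float = 0.0
    beat_frequency: float = 0.0
    power_fraction: float = 0.4
    direction_power: tuple[float, float] = (-1.0, 0.0)
    diffusion_coefficient: float = 0.0

    KINDS = ("static", "uniform_translation", "brownian", "beating")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if self.speed_power < 0 or self.speed_recovery < 0:
            raise ValueError("speeds must be non-negative")
        d = np.asarray(self.direction_power, dtype=float)
        norm = float(np.hypot(*d))
        if norm == 0:
            raise ValueError("direction_power must be a non-zero vector")
        object.__setattr__(self, "direction_power", (d[0] / norm, d[1] / norm))
        if self.kind == "beating":
            if self.beat_frequency <= 0:
                raise ValueError("beat_frequency must be positive for beating motion")
            if not 0 < self.power_fraction < 1:
                raise ValueError("power_fraction must lie in (0, 1)")
        if self.kind == "brownian" and self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive for brownian motion")

    @classmethod
    def static(cls) -> "MotionProgram":
        return cls(kind="static")

    @classmethod
    def uniform(cls, speed: float, direction: tuple[float, float] = (-1.0, 0.0)) -> "MotionProgram":
        return cls(kind="uniform_translation", speed_power=speed, direction_power=direction)

    @classmethod
    def brownian(cls, diffusion_coefficient: float) -> "MotionProgram":
        return cls(kind="brownian", diffusion_coefficient=diffusion_coefficient)

    @classmethod
    def beating(
        cls,
        beat_frequency: float = 5.0,
        speed_power: float = 250.0,
        speed_recovery: float = 150.0,
        power_fraction: float = 0.4,
        direction_power: tuple[float, float] = (-1.0, 0.0),
    ) -> "MotionProgram":
        """Asymmetric beat cycle; defaults mirror a healthy-cilium regime
        (5 Hz, 0.25 mm/s power and 0.15 mm/s recovery stroke)."""
        return cls(
            kind="beating",
            beat_frequency=beat_frequency,
            speed_power=speed_power,
            speed_recovery=speed_recovery,
            power_fraction=power_fraction,
            direction_power=direction_power,
        )

    def velocity_at(self, t: float) -> tuple[float, np.ndarray]:
        """Programmed (speed, unit direction) at time t (brownian excluded)."""
        d = np.asarray(self.direction_power, dtype=float)
        if self.kind == "static":
            return 0.0, d
        if self.kind == "uniform_translation":
            return self.speed_power, d
        if self.kind == "beating":
            phase = (t * self.beat_frequency) % 1.0
            if phase < self.power_fraction:
                return self.speed_power, d
            return self.speed_recovery, -d
        raise ValueError("brownian motion has no deterministic instantaneous velocity")


@dataclass(frozen=True)
class SimConfig:
    """Imaging/acquisition parameters of a simulated recording.

    ``psf_radius`` is the 1/e half-width (Gaussian sigma) of the coherent PSF
    in micrometres and sets the speckle grain size; it must span at least one
    pixel or the speckle would alias.  The default 0.2 um matches the
    diffraction-limited grain lambda/(2 NA) of a 405 nm / NA 1.0 system.  The
    default effective pixel size is the 11 um camera pixel demagnified 60x.  ``noise_model`` is "none",
    "poisson" (noise_param = mean photons per pixel at the mean intensity) or
    "gaussian" (noise_param = additive sigma in intensity units).
    """

    field_extent: tuple[float, float]
    n_frames: int
    frame_rate: float = 3000.0
    psf_radius: float = 0.2
    effective_pixel_size: float = 11.0 / 60.0
    wavelength: float = 405.0
    detection_na: float = 1.0
    noise_model: str = "none"
    noise_param: float = 0.0
    dephasing: str = "wavevector"
    dephasing_split: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.psf_radius <= 0:
            raise ValueError("psf_radius must be positive")
        if self.effective_pixel_size <= 0:
            raise ValueError("effective_pixel_size must be positive")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError("noise_model must be none, poisson or gaussian")
        if isinstance(self.dephasing, bool):  # back-compat style convenience
            object.__setattr__(self, "dephasing", "wavevector" if self.dephasing else "none")
        if self.dephasing not in ("none", "wavevector", "diffusion", "mixed"):
            raise ValueError("dephasing must be none, wavevector, diffusion or mixed")
        if not 0.0 <= self.dephasing_split <= 1.0:
            raise ValueError("dephasing_split must lie in [0, 1]")
        h, w = self.field_extent
        px = self.effective_pixel_size
        if abs(h / px - round(h / px)) > 1e-6 or abs(w / px - round(w / px)) > 1e-6:
            raise ValueError("field_extent must be an integer number of pixels")

    @property
    def shape(self) -> tuple[int, int]:
        px = self.effective_pixel_size
        return (int(round(self.field_extent[0] / px)), int(round(self.field_extent[1] / px)))

    @classmethod
    def from_pixels(cls, shape: tuple[int, int], n_frames: int, **kwargs) -> "SimConfig":
        """Convenience constructor sizing the field from a pixel grid."""
        px = kwargs.get("effective_pixel_size", 11.0 / 60.0)
        extent = (shape[0] * px, shape[1] * px)
        return cls(field_extent=extent, n_frames=n_frames, **kwargs)


@dataclass
class GroundTruthTrace:
    """Programmed per-frame motion: instantaneous speed (um/s) and unit direction."""

    times: np.ndarray
    speeds: np.ndarray
    directions: np.ndarray


def render_speckle_frame(
    field: ScattererField,
    config: SimConfig,
    positions: Optional[np.ndarray] = None,
    phases: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Render one speckle frame: |coherent sum of PSF-weighted phasors|^2.

    ``positions`` overrides the field's resting positions (same shape);
    ``phases`` adds a per-scatterer phase in radians.  Contributions wrap
    around the field (torus), so a rigid integer-pixel translation of all
    scatterers cyclically shifts the frame exactly.
    """
    px = config.effective_pixel_size
    w = config.psf_radius
    if w < px:
        raise ValueError("psf_radius below one pixel would alias the speckle")
    H, W = config.shape
    pos = field.positions if positions is None else np.asarray(positions, dtype=np.float64)
    if pos.shape != field.positions.shape:
        raise ValueError("positions must match the scatterer field shape")
    amp = field.amplitudes
    if phases is not None:
        amp = amp * np.exp(1j * np.asarray(phases))

    k = int(math.ceil(3.5 * w / px))
    k = min(k, min(H, W) // 2)  # stamp never wraps onto itself
    off = np.arange(-k, k + 1)
    centre = np.round(pos / px).astype(np.int64)  # (N, 2)
    rows = (centre[:, 0:1] + off) % H  # (N, K)
    cols = (centre[:, 1:2] + off) % W
    # separable Gaussian evaluated at the exact (non-wrapped) distances
    dr = (centre[:, 0:1] + off) * px - pos[:, 0:1]
    dc = (centre[:, 1:2] + off) * px - pos[:, 1:2]
    gr = np.exp(-dr * dr / (2.0 * w * w))
    gc = np.exp(-dc * dc / (2.0 * w * w))
    contrib = (amp[:, None, None] * gr[:, :, None]) * gc[:, None, :]  # (N, K, K)
    idx = (rows[:, :, None] * W + cols[:, None, :]).ravel()
    flat = contrib.ravel()
    e_re = np.bincount(idx, weights=flat.real, minlength=H * W)
    e_im = np.bincount(idx, weights=flat.imag, minlength=H * W)
    intensity = (e_re * e_re + e_im * e_im).reshape(H, W)
    return intensity


def _apply_noise(frames: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "none":
        return frames
    if config.noise_model == "poisson":
        photons = config.noise_param
        if photons <= 0:
            raise ValueError("poisson noise requires noise_param > 0 (photons per pixel)")
        scale = photons / max(frames.mean(), 1e-300)
        return rng.poisson(frames * scale).astype(np.float64) / scale
    return np.clip(frames + rng.normal(0.0, config.noise_param, size=frames.shape), 0.0, None)


def simulate_stack(
    field: ScattererField,
    motion: MotionProgram,
    config: SimConfig,
) -> tuple[SpeckleStack, GroundTruthTrace]:
    """Render a full stack while advancing scatterers per the motion program.

    Returns the stack plus the ground-truth per-frame speed trace.  The speed
    reported at frame t is the programmed speed used to advance from frame t
    to t+1 (for Brownian motion, the mean per-scatterer step magnitude over
    the frame interval).

    Identical inputs (including ``config.seed``) produce bit-identical stacks.
    """
    rng = np.random.default_rng(config.seed)
    n = len(field.positions)
    T = config.n_frames
    dt = 1.0 / config.frame_rate
    H, W = config.shape
    extent = np.asarray(field.extent)
    if tuple(extent) != tuple(config.field_extent):
        raise ValueError("field and config extents disagree")

    # total dephasing rate: gamma = pi NA / lambda per um of travel, so that
    # g1(tau) = exp(-gamma v tau) and the Siegert pipeline recovers v exactly
    gamma = math.pi * config.detection_na / (config.wavelength * 1e-3)  # 1/um
    split = config.dephasing_split
    q = None
    gamma_diff = 0.0
    if config.dephasing in ("wavevector", "mixed"):
        g_q = gamma * (split if config.dephasing == "mixed" else 1.0)
        # isotropic 2-D Cauchy (multivariate t, nu=1): characteristic function
        # exp(-g_q * |d|)  =>  exponential g1 decay with the net displacement;
        # reversed motion re-correlates (phases retrace)
        z = rng.standard_normal((n, 2))
        denom = np.abs(rng.standard_normal((n, 1)))
        denom[denom < 1e-12] = 1e-12
        q = g_q * z / denom
    if config.dephasing in ("diffusion", "mixed"):
        # annealed phase random walk, variance 2*g_d per um of path length:
        # every scatterer decorrelates at the same rate, irreversibly
        gamma_diff = gamma * ((1.0 - split) if config.dephasing == "mixed" else 1.0)
    diff_phase = np.zeros(n)

    displacement = np.zeros((n, 2))  # accumulated, unwrapped
    frames = np.empty((T, H, W), dtype=np.float64)
    speeds = np.empty(T)
    directions = np.empty((T, 2))
    times = np.arange(T) * dt

    max_step = min(extent)
    for t in range(T):
        wrapped = np.mod(field.positions + displacement, extent)
        phases = None
        if q is not None:
            phases = (q * displacement).sum(axis=1)
        if gamma_diff > 0:
            phases = diff_phase if phases is None else phases + diff_phase
        frames[t] = render_speckle_frame(field, config, positions=wrapped, phases=phases)

        if motion.kind == "brownian":
            step = rng.normal(0.0, math.sqrt(2.0 * motion.diffusion_coefficient * dt), size=(n, 2))
            path = np.hypot(step[:, 0], step[:, 1])
            speeds[t] = float(np.mean(path)) / dt
            directions[t] = (0.0, 0.0)
        else:
            speed, direction = motion.velocity_at(times[t])
            step = (speed * dt) * direction[None, :]
            path = np.full(n, speed * dt)
            speeds[t] = speed
            directions[t] = direction
        if np.max(np.abs(step)) >= max_step:
            raise ValueError("per-frame displacement exceeds the field extent")
        if gamma_diff > 0:
            diff_phase = diff_phase + rng.standard_normal(n) * np.sqrt(2.0 * gamma_diff * path)
        displacement = displacement + step

    frames = _apply_noise(frames, config, rng)
    stack = SpeckleStack(
        frames=frames,
        frame_rate=config.frame_rate,
        effective_pixel_size=config.effective_pixel_size,
        wavelength=config.wavelength,
        detection_na=config.detection_na,
    )
    return stack, GroundTruthTrace(times=times, speeds=speeds, directions=directions)
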