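# Methods

## Scope

`ciliaspeckle` quantifies the motion of motile cilia from high-speed laser
speckle recordings. It implements the computational chain only: a synthetic
dynamic-speckle simulator with programmable cilia-like motion, per-pixel
moving-window autocorrelation velocimetry, ciliary beat frequency (CBF) and
beat-pattern (CBP) metrics, and ensemble-correlation particle image
velocimetry (PIV). Optics (light-sheet generation, oblique geometry), cell
culture and any hardware control are out of scope.

## Velocimetry model

The temporal intensity autocorrelation of dynamic speckle at lag τ follows
the Siegert relation

    g2(τ) = 1 + β |g1(τ)|²,   g1(τ) = exp(−(τ/τc)^n),

so g2(τ) = 1 + β·exp(−2(τ/τc)^n). β ∈ (0, 1] is the setup-dependent
coherence factor, τc the decorrelation time and n the scattering-regime
exponent; single scattering in a transparent sample corresponds to n = 1,
which is the pipeline default. The exponent placement (squaring the
stretched-exponential g1) is deliberate; the alternative reading
1 + β·exp(−(τ/τc)^(2n)) coincides with it at n = 1.

The decorrelation time maps to an absolute speed via

    v = λ / (π · NA · τc)

with λ the illumination wavelength and NA the detection numerical aperture.
With λ = 405 nm and NA = 1.0, τc = 1.29×10⁻⁴ s corresponds to 1.0 mm/s.

### Estimation

g2 is estimated per pixel inside a moving time window (default 20 frames,
stride 10 frames, lags 1..window/2 frames):
g2(k) = ⟨I(t)·I(t+k)⟩ / ⟨I⟩², all valid pairs in the window, window mean in
the denominator. Every window start at a multiple of the stride below the
frame count produces an output map; truncated final windows keep
min(max_lag, length−2) lags and need at least 3 (length ≥ 5). With 3000
frames at the defaults this gives exactly 300 velocity maps. Timestamps are
nominal window centres on a uniform grid.

### Fitting

Two fit strategies exist:

* **`fit_siegert` (joint fit)** — weighted nonlinear least squares for
  (β, τc), damped Gauss–Newton on (β, ln τc) seeded by a weighted
  log-linear regression of ln(g2−1) on τ^n, weights the pair count per lag.
  β is constrained to (0, 1] (it is physically a coherence factor; a fit at
  the bound stays valid). Noiseless model samples are recovered to machine
  precision. Fits are invalid when the first-lag decay is below the noise
  floor (default 0.05), when τc pins at a bound (defaults
  0.1/frame-rate .. 100 × window duration), or when the residual exceeds an
  optional cap. This is the right tool for well-sampled correlograms.

* **`velocity_map_stack` default (contrast-anchored fit)** — on 20-frame
  windows the joint problem is a shallow ridge: many (small β, long τc)
  pairs fit a fast decay equally well, and batch medians inherit a large
  bias. β is however directly measurable as the model's own zero-lag
  point, g2(0) − 1 = Var(I)/⟨I⟩² (the squared temporal speckle contrast),
  so the pipeline anchors β per pixel and window and fits only τc.
  Because both the correlogram and the contrast are normalized by the
  window sample mean, whose fluctuations correlate with the signal, the
  fit uses the first-order finite-window expectation
  E[ĝ2(k)] = (1 + β·r^k)/(1 + β·S/T²) with r = exp(−2Δt/τc) and
  S = T + 2Σ(T−m)r^m, and recovers β from
  E[contrast²] = β(1 − S/T²)/(1 + β·S/T²). For long windows S/T² → 0 and
  the correction vanishes. The joint fit remains available as
  `beta_mode="free"`.

Invalid pixels are masked, never zeroed; all spatial averages downstream
exclude them. Speed maps are mm/s; ROI boxes are half-open
[row0,row1)×[col0,col1), row-major, origin top-left.

### Measurement windows

Window length is a measurement choice matched to the dynamics: beating
records use the 20-frame moving window (≈6.7 ms at 3000 fps) so the
waveform resolves individual strokes; steady motions (calibration
translations) are analysed with a single record-length window, which the
same code path handles (`window_frames = n_frames`). Short windows simply
cannot constrain τc at the extremes of a wide speed range.

On simulated uniform translation at 0.1–0.5 mm/s (405 nm, NA 1.0, record
length 1 s) the spatial-median recovered speed is within ~10–15 % of truth
at every speed and strictly monotone; the residual systematic is the
mixture of the speckle-envelope decay (see below) and higher-order
estimator bias not captured by the first-order correction.

## Synthetic speckle

A frame is |Σ_j a_j·exp(iφ_j)·h(x − x_j)|² over discrete scatterers with
circular-Gaussian complex amplitudes a_j, imaged through a Gaussian
coherent PSF h of radius `psf_radius` (default 0.2 µm ≈ λ/2NA for the
405 nm / NA 1.0 reference system; must span ≥ 1 pixel). Scatterers live on
a torus (re-entry keeps density stationary). Dense fields — at least ~10
scatterers per speckle grain, e.g. density 100 µm⁻² at the default grain —
give fully developed speckle (intensity contrast σ/µ = 1); sparser fields
break the Gaussian-field assumption behind the Siegert relation and
visibly bias the velocimetry.

Scatterer motion follows a `MotionProgram`: static, uniform translation,
Brownian, or an asymmetric beat cycle alternating a power stroke
(`power_fraction` of the period at `speed_power` along `direction_power`)
with a reversed recovery stroke for the rest of the period. Defaults
mirror a healthy-cilium regime: 5 Hz, 0.25/0.15 mm/s, power fraction 0.4.
The ground-truth trace records the programmed speed and direction at every
frame.

### Dephasing

Pure envelope translation decorrelates a pixel as a Gaussian in τ, not the
exponential the n = 1 velocimetry model assumes. The simulator therefore
adds per-scatterer dynamic phases (config switch `dephasing`):

* `"wavevector"` (default): each scatterer carries a fixed transverse
  scattering-wavevector offset q_j drawn from an isotropic 2-D Cauchy
  distribution with scale πNA/λ; its phase advances by q_j·(net
  displacement). The ensemble field correlation is then exactly
  g1 = exp(−πNA·v·τ/λ), i.e. τc = λ/(πNA·v) — the regime in which the
  speed conversion is exact. The phases are reversible: a reversing stroke
  re-correlates the speckle, which is what produces the characteristic
  dips between power and recovery plateaus in measured beat waveforms.
* `"diffusion"`: an annealed phase random walk with the same rate
  (variance 2πNA/λ per µm of path), irreversible, with no quenched rate
  disorder — every scatterer decorrelates identically.
* `"mixed"`: both, weighted by `dephasing_split`.
* `"none"`: rigid translation only. On the torus, integer-pixel per-frame
  translations reproduce exact cyclic shifts — the right fixture for PIV
  tests, where the displacement signal rather than speckle boiling is
  under test.

The envelope translation always contributes a second, Gaussian decay
factor exp(−(vτ)²/(2·psf_radius²)) to g2; at the defaults it accelerates
the fitted decay by a few percent (speed read slightly high), which is
part of the quoted velocimetry accuracy.

Optional noise: Poisson shot noise (parameterized by mean photons/pixel)
or additive Gaussian, applied after intensity formation; default off so
analytic checks stay clean.

What the simulator does **not** emulate: light-sheet beam profiles and
oblique-plane geometry, multiple scattering, out-of-plane motion,
camera exposure-time blur within a frame, spatially varying β, or the
smooth acceleration profile of real cilia (strokes switch speed
instantaneously). Real beat waveforms are spiky, with near-baseline
velocity between strokes; the rectangular program instead produces
two-level plateau waveforms. Passing tests demonstrate the estimator
chain, not biological realism of the motion model.

## Beat metrics

The ROI waveform is the per-frame mean speed over valid pixels (missing
frames are NaN-flagged). CBF is the largest magnitude-FFT peak above a DC
cutoff (default 0.5 Hz; the record must span at least 1/cutoff), after
mean removal, 4× zero-padding and parabolic sub-bin refinement — the raw
bin spacing of a 2-s record is 0.5 Hz, so sub-bin interpolation is what
makes ~0.01 Hz-scale readouts possible.

Stroke peaks: local maxima above a prominence threshold (default 25 % of
the 5th–95th percentile range) with a minimum separation (default 25 % of
the dominant period). Detected peak values are then classified:

* *uniform* (spread below the prominence threshold, e.g. a sinusoid) and
  *spiky* (two balanced, strictly alternating value classes at about two
  peaks per period — the regime of real cilia waveforms): consecutive
  peaks are paired into cycles, the larger of each pair being the power
  peak.
* *plateau* (rectangular programs; only the power level raises prominent
  peaks): one power peak per period is kept (separation ≥ 0.55 period,
  value above the midpoint between power level and baseline) and the
  recovery peak is the highest sample between consecutive power peaks
  that sits below that midpoint.

Cycle metrics: the beat period is the mean ± sample SD of intervals
between consecutive power peaks; stroke durations are FWHMs at half the
peak prominence with linear interpolation (flagged unmeasurable at record
edges or for non-local-maximum plateau points); `duration_ratio` is mean
power FWHM / mean recovery FWHM; `high_to_low_ratio` is the mean of
per-cycle peak-value ratios (a per-cycle mean, not a ratio of means —
the latter cannot reproduce reported values from mean stroke speeds
alone). All metrics except the absolute stroke speeds are invariant to
amplitude scaling.

Because the simulator's plateaus are compressed by the residual
velocimetry bias (power read ~6 % low, recovery ~25 % high at the
defaults), measured high-to-low ratios on simulated beats (~1.2) sit well
below the programmed 1.67; the ratio is nevertheless strictly monotone in
the programmed asymmetry, which is what the metric is for.

## Ensemble PIV

Square interrogation windows (default 8 px, step 4 px; border windows
dropped) are compared between consecutive frames. For each pair and
window the zero-padded linear cross-correlation of raw intensities is
divided by the per-offset overlap count and reduced by the product of the
per-offset partial means — the sample cross-covariance at every
displacement, normalized by window standard deviations. Naive circular or
zero-padded correlation of mean-subtracted windows carries a triangular
loss-of-pairs taper that drags broad speckle peaks toward zero
displacement (≈0.25 px error at a true 0.5 px shift with 8-px windows);
the per-offset normalization removes this. Planes are averaged over all
pairs in the requested range (the ensemble), the peak is searched within
±window/2 (larger displacements surface as low-quality vectors, never
aliased ones), and refined per axis by a 3-point Gaussian fit (ties broken
toward the smaller displacement; fallback parabolic). Validation: primary
/secondary peak ratio ≥ 1.3 plus a 3×3 neighbourhood median test (3 MADs,
0.1 px floor); failing vectors are masked, not interpolated.

Accuracy on dense noiseless speckle: integer shifts exact in the integer
part with sub-pixel residual ≤ 0.1 px; 0.2–0.8 px shifts recovered within
≈0.05 px. Phase-resolved fields restricted to power- and recovery-stroke
intervals point in opposite directions for beating programs; with
asymmetric speeds and equal stroke durations the full-record ensemble
shows a net displacement along the power-stroke direction. Row axis
points down in array coordinates, so an "upward" power stroke is v < 0;
the CLI quiver plot flips the vertical axis for display.

## Determinism and sizes

Every stochastic step draws from `numpy.random.default_rng` seeded from
the run configuration; identical config + seed reproduces byte-identical
artifacts, including TIFF and CSV outputs. The bundled analyses use
patches of 16–64 px and records of 1–2 s (3000–6000 frames) — small
fields with the reference pixel pitch (11 µm / 60×) chosen so the full
suite completes in minutes on one core; all estimator properties quoted
above were measured at those sizes.

## Known limitations

* The velocimetry carries a residual ~10 % systematic at the defaults
  (envelope decay plus higher-order finite-window bias); quantities
  derived from speed magnitudes inherit it.
* The finite-window bias model is first-order; second-order terms matter
  most where τc approaches the window length.
* Stroke-duration FWHMs are only meaningful for spiky waveforms; on
  rectangular simulated beats they describe plateau widths.
* The peak-regime classifier can misread records shorter than ~4 beats
  or with strong amplitude drift; period estimates carry the detected
  peak set.
* `n ≠ 1` fits are supported by the joint fit only, and no calibration
  study for multiple scattering is included.
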