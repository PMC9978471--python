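# ciliaspeckle

Quantitative analysis of motile-cilia dynamics from high-speed laser
speckle recordings.

Coordinated ciliary beating drives mucociliary clearance in the airway
epithelium, and its two clinical descriptors — the ciliary beat frequency
(CBF) and the richer beat-pattern (CBP) indicators such as stroke speeds,
stroke durations and beat direction — are hard to measure label-free.
Dynamic laser speckle offers a route: coherent light scattered by moving
cilia produces a speckle pattern whose temporal decorrelation encodes
absolute scatterer speed. This package implements the full computational
chain for that measurement, for researchers analysing high-frame-rate
speckle stacks of ALI-cultured airway epithelium (or any comparable
dynamic-speckle recording), together with a synthetic speckle simulator
that provides exact ground truth for every stage.

## Model

Per pixel, inside a moving time window (default 20 frames), the intensity
autocorrelation is fitted with the Siegert relation

```
g2(τ) = 1 + β · exp(−2 (τ/τc)^n),        n = 1 (single scattering)
```

and the decorrelation time τc is converted to an absolute speed

```
v = λ / (π · NA · τc)
```

(λ illumination wavelength, NA detection numerical aperture), yielding a
time series of speed maps in mm/s. ROI-averaged waveforms then give the
CBF (zero-padded magnitude FFT with sub-bin refinement) and the CBP
metrics: beat period from high-peak intervals, power/recovery stroke
speeds and FWHM durations, duration ratio and high-to-low peak ratio.
Directional information comes from ensemble-correlation PIV on the raw
speckle (8-px interrogation windows, 4-px step), optionally restricted to
power- or recovery-stroke phase intervals.

Modules: `speckle_sim` (simulator), `velocimetry` (g2 / Siegert /
velocity maps), `beat` (CBF + CBP metrics), `piv` (ensemble PIV),
`io` + `cli` (TIFF/JSON/CSV formats, YAML run configs, `ciliaspeckle`
command). See `docs/methods.md` for the estimator details and design
choices.

## Worked example

Simulate a 2-s recording of a 5 Hz asymmetric beat (power stroke
0.25 mm/s, recovery 0.15 mm/s) at the reference acquisition settings
(3000 fps, 405 nm, NA 1.0, 11 µm camera pixels at 60×), then run the
velocimetry and beat analysis:

```python
import numpy as np
from ciliaspeckle import (MotionProgram, ScattererField, SimConfig,
                          simulate_stack, velocity_map_stack, roi_waveform,
                          summarize_beat)

cfg = SimConfig.from_pixels((24, 24), n_frames=6000, frame_rate=3000.0, seed=5)
field = ScattererField.random(cfg.field_extent, density=100.0,
                              rng=np.random.default_rng(5))
motion = MotionProgram.beating(beat_frequency=5.0, speed_power=250.0,
                               speed_recovery=150.0, power_fraction=0.4)
stack, truth = simulate_stack(field, motion, cfg)

velocity = velocity_map_stack(stack)      # 20-frame window, 10-frame stride
waveform = roi_waveform(velocity)         # ROI mean over valid pixels
summary = summarize_beat(waveform)

print(f"CBF            {summary.cbf_hz:.2f} Hz   (programmed 5.00 Hz)")
print(f"beat period    {summary.period_mean:.3f} +/- {summary.period_sd:.3f} s")
print(f"power stroke   {summary.power_velocity_mean:.3f} mm/s (programmed 0.250)")
print(f"recovery       {summary.recovery_velocity_mean:.3f} mm/s (programmed 0.150)")
print(f"high/low ratio {summary.high_to_low_ratio:.2f}")
```

prints

```
CBF            5.00 Hz   (programmed 5.00 Hz)
beat period    0.196 +/- 0.033 s
power stroke   0.239 mm/s (programmed 0.250)
recovery       0.194 mm/s (programmed 0.150)
high/low ratio 1.23
```

The CBF and beat period are recovered essentially exactly; the stroke
speeds carry the velocimetry's residual systematic (power a few percent
low, recovery high — see `docs/methods.md`), so the measured high/low
ratio understates the programmed 1.67 while remaining strictly monotone
in the true asymmetry.

The same pipeline is available from the shell:

```
ciliaspeckle simulate --motion beating --frames 6000 --shape 24 24 \
    --density 100 --seed 5 --out stack.tif
ciliaspeckle velocity stack.tif --out run
ciliaspeckle beat run --out metrics/
ciliaspeckle piv stack.tif --phase-intervals 0.0:0.08,0.08:0.2 --out piv/
```

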