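# nirtwin

A digital twin of an sCMOS-camera-based continuous-wave fNIRS instrument and
its complete computational chain, built for engineers and methodologists who
want to rehearse and verify every validation experiment such a system goes
through — instrument QC, optical-phantom calibration, and task hemodynamics —
entirely on synthetic data.

Camera-based fNIRS replaces discrete photodiodes with a single 12-bit sCMOS
sensor: every detector fibre projects a circular speckle spot onto the chip
(one per wavelength, 695/830 nm split onto the two sensor halves), and the
measurement is the *mean gray value* (MGV) over a fixed 102-pixel-radius
region of interest. Seventeen sources and sixteen detectors in a 3 × 11
checkerboard grid at ρ = 30 mm pitch form 52 source–detector channels;
sources fire in a 4-group time-division-multiplexed (TDM) cycle of
4 × (25 + 25) ms, giving a 5 Hz channel sampling rate.

The package implements, end to end:

- **Geometry & TDM** — checkerboard optode grids, channel enumeration,
  conflict-free source grouping with a validity certificate.
- **Sensor twin** — the photon-transfer model
  `ADU = clip(round((Poisson(ηλPt/hc) + N(0, Q))/CG) + bias, 0, 4095)` with
  datasheet constants (Q = 3.57 e⁻, CG = 2.33 e⁻/ADU, η₆₉₅ = 84.06 %,
  η₈₃₀ = 53.33 %, t = 25 ms), speckle-spot frame rendering, and laser-safety
  arithmetic (fibre-tip irradiance vs ANSI skin MPE).
- **Phantom forward models** — semi-infinite extrapolated-boundary CW
  diffusion reflectance (μ_eff = √(3 μ_a(μ_a + μ_s′))), van Staveren
  Intralipid scattering, India-ink titration presets, a blood-doped phantom
  with an embedded haemoglobin extinction table, deoxygenation courses,
  block-design task hemodynamics, and instrument drift streams.
- **Extraction** — ROI averaging, TDM demultiplexing, emitter-power
  normalisation, saturation flagging.
- **QC metrics** — two-state SNR `20·log₁₀(mean ΔMGV / sd ΔMGV)`,
  theoretical/actual noise-equivalent power, dynamic optical range
  `10·log₁₀(MGV_max/MGV_min)`, and the drift triple (linear %/h rate,
  overlapping Allan deviation, ±3σ occupancy).
- **Hemodynamics pipeline** — titration-based channel pruning, windowed
  motion-artifact masking (STDthresh = 10, AMPthresh = 5, 0.5 s guard),
  >5 %-contamination channel rejection, zero-phase 0.01–0.2 Hz Butterworth
  filtering, ΔOD → modified Beer–Lambert inversion
  `ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·L·DPF(λ)`, SO₂ estimation,
  square-root variance stabilisation, and the R²/Pearson–Spearman statistics.

## Worked example

```python
import nirtwin as nt

grid  = nt.build_grid(3, 11, pitch_mm=30.0)
cmap  = nt.enumerate_channels(grid)
sched = nt.build_tdm_schedule(grid, n_groups=4, on_ms=25, off_ms=25)
print(f"array: {grid.n_sources} sources / {grid.n_detectors} detectors, "
      f"{len(cmap)} channels")
print(f"TDM cycle {sched.cycle_ms:.0f} ms -> sampling rate {sched.sampling_rate_hz:.1f} Hz")

irr = nt.source_irradiance(nt.SourceSpec())
print(f"fibre-tip irradiance {irr[695.0]:.1f} mW/cm2 "
      f"(skin MPE: {nt.mpe_skin(695):.0f} @695nm, {nt.mpe_skin(830):.2f} @830nm)")
print(f"DOR: {nt.dynamic_optical_range(4095, 1.87):.2f} dB @695nm, "
      f"{nt.dynamic_optical_range(4095, 1.92):.2f} dB @830nm")
```

prints

```
array: 17 sources / 16 detectors, 52 channels
TDM cycle 200 ms -> sampling rate 5.0 Hz
fibre-tip irradiance 56.6 mW/cm2 (skin MPE: 200 @695nm, 363.94 @830nm)
DOR: 33.40 dB @695nm, 33.29 dB @830nm
```

i.e. the 52-channel array samples at 5 Hz, the 4 mW / 3 mm-tip emitters sit
well below the skin exposure limits at both wavelengths, and the camera's
dynamic optical range spans ~33 dB between its saturating and
noise-equivalent gray values.

A full phantom experiment is one call; here the high-absorption ink
titration (μ_a 0.03366 → 0.04639 mm⁻¹) through the complete
simulator + extraction chain:

```python
from nirtwin import experiments, phantoms

res = experiments.run_titration_experiment(
    phantoms.high_absorption_titration(9), experiments.default_rig(), seed=104)
print(round(res.min_r2_sqrt, 4))   # -> 0.9648  (linearity of the sqrt-signal)
```

The `nirtwin` CLI wraps the same runners
(`nirtwin simulate|extract|qc|pipeline|report`, all deterministic under
`--seed`, configured by a TOML file).

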