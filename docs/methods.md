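# Methods

This note records the models behind `nirtwin`, the defaults and their units,
the choices made where the underlying instrument description left the design
open, and what the synthetic experiments do and do not demonstrate.

## Instrument model

**Array and multiplexing.** Optodes occupy a rows × cols grid with one role
per node in a checkerboard; with sources on the corners a 3 × 11 grid holds
17 sources and 16 detectors and its 52 orthogonally adjacent source–detector
pairs are the measurement channels (grid-graph edge count
`rows·(cols−1) + (rows−1)·cols`). Channel ordering is row-major by detector,
then by source; published channel numberings of comparable instruments are
pictorial only, so ids are not guaranteed to match any particular device.
Sources are partitioned into TDM groups such that no detector has two
same-group neighbours (otherwise their contributions are inseparable in the
frame). Grouping uses deterministic greedy colouring of the shared-detector
conflict graph in source-id order; should greedy exceed the requested group
count, the closed-form 4-colouring by parity of the rotated sublattice
coordinates `u=(r+c)/2, v=(c−r)/2` (the conflict graph is a king graph in
these coordinates) is used instead. Infeasible requests raise an error
carrying a witnessing (detector, source, source) triple when available.
Cycle time is `n_groups·(on+off)` ms; the default 4 × (25+25) ms gives 5 Hz.

**Sensor.** Pixels follow the standard sCMOS photon-transfer model: expected
photoelectrons `μ = P·t·η_λ·λ/(hc)/N` over the N spot pixels, then

    ADU = clip( round( (Poisson(μ) + Normal(0, Q)) / CG ) + bias, 0, 4095 )

with read noise Q = 3.57 e⁻ rms, conversion gain CG = 2.33 e⁻/ADU, 12-bit
ceiling, 25 ms exposure, η = 0.8406/0.5333 at 695/830 nm. Shot noise,
quantisation and the pedestal can be disabled independently, which yields the
exactly linear sensor used by the round-trip identities. Spots are rendered
with uniform mean flux — MGV averaging destroys intra-spot structure, so
speckle texture (optional multiplicative contrast) defaults to off. Frames
are captured during on-slots only; dark frames during off-slots are not
rendered by default.

*Pedestal.* The experiment runners use a 100 ADU camera pedestal
(`bias_adu`), subtracted again at extraction. Without it, clipping the read
noise at zero biases a dark ROI's mean by ≈ Q/(CG·√2π) ≈ 0.6 ADU and halves
the response slope for signals below the read noise, which corrupts exactly
the deep-attenuation end of the blood-phantom course. Real sCMOS cameras
carry such an offset for the same reason. The bare model (bias 0) remains
the default of `SensorSpec` itself.

*ROI discretisation.* A pixel belongs to a spot/ROI iff its centre lies
within the radius (Euclidean); for the 102-px radius this gives N ≈ 32 685
pixels, within one part in 10³ of the area formula π·102² that the NEP
constants quote (N = 32 686 is kept as the NEP default).

**Safety arithmetic.** Fibre-tip irradiance is `P/(π(d/2)²)`; the skin MPE
follows the ANSI Z136.1 CW convention `200·C_A` mW/cm² with `C_A = 1` below
700 nm and `10^{2(λ_μm−0.700)}` up to 1050 nm. The default 4 mW / 3 mm
source gives 56.6 mW/cm², below 200 (695 nm) and 363.94 (830 nm).

## Forward optics

Relative detected power comes from the semi-infinite extrapolated-boundary
CW diffusion solution (Kienle/Patterson form): diffusion coefficient
`D = 1/(3(μ_a+μ_s'))`, effective attenuation `μ_eff = √(3μ_a(μ_a+μ_s'))`,
isotropic source at depth `z0 = 1/(μ_a+μ_s')`, mirror image above the
extrapolated boundary `z_b = 2AD` with the Groenhuis internal-reflection
parameter at n = 1.33 (liquid phantoms). Only relative intensity is used
anywhere downstream. Media with `μ_s' ≤ μ_a` are a hard error; `μ_s'/μ_a <
10` warns. The phantom geometry between opposing arrays in a large tank is
ambiguous in descriptions of such rigs; this package models reflectance at
ρ = 30 mm (the array pitch). Transmission across tens of centimetres of a
μ_s' = 2.3 mm⁻¹ medium would be unmeasurable, so it is not offered.

**Scattering recipe.** Intralipid reduced scattering follows the van
Staveren empirical model (μ_s = 16·λ_μm^{−2.4} mm⁻¹ for 10 % lipid,
g = 1.1 − 0.58·λ_μm, linear in lipid fraction; valid 400–1100 nm). The
standard recipe μ_s' = 2.3 mm⁻¹ at 695 nm (≈ 2 % lipid) implies 1.89 mm⁻¹
at 830 nm, which all runners use for wavelength consistency.

**Absorbers.** Ink titration presets reproduce the three published μ_a
ranges at 695 nm exactly (baseline 0.00899–0.01100, low 0.01192–0.01254,
high 0.03366–0.04639 mm⁻¹) with the per-µL specific absorption calibrated
from the endpoints (2 µL increments, default 9 steps → 10 points). At
830 nm the non-water part is scaled by 0.85 (India ink is spectrally nearly
flat, mildly decreasing into the NIR) and the water background swapped
(0.0005/0.0029 mm⁻¹ at 695/830 nm). The blood phantom holds 5 % whole blood
by volume; with whole-blood haemoglobin ≈ 2.3 mM the mixture tHb is
0.115 mM, and `μ_a = ln10·tHb·(SO₂·ε_HbO + (1−SO₂)·ε_HbR) + background`.
Extinction coefficients are a compact table compiled from the standard Prahl
(Oregon Medical Laser Center) tabulation, linearly interpolated, in
mm⁻¹·mM⁻¹ (decadic).

## Experiment generators

All generators are bit-for-bit reproducible under a fixed seed; the CLI
derives named sub-seeds (`sensor`, `titration`, `deoxygenation`, …) from one
master seed so stages stay reproducible when run separately.

- **Deoxygenation course**: logistic in normalised time, rescaled to hit 1.0
  at t = 0 and the floor (default 0) at t = duration exactly, hence monotone
  non-increasing — dithionite kinetics are not published, and any monotone
  course is accepted by the pipeline. Blood-gas reference samples are exact
  course readings at evenly spaced times (analyser noise optional, default
  off). Default: 600 s, 12 samples.
- **Task hemodynamics**: 30/60/60 s rest–task–rest boxcar convolved with the
  canonical double-gamma kernel, peak ΔHbO = 1 µM with ΔHbR = −0.3 µM
  (typical evoked prefrontal amplitudes); physiological sinusoids with
  random phases (cardiac 1.1 Hz at 0.2 µM, respiratory 0.3 Hz at 0.1 µM,
  Mayer 0.1 Hz at 0.1 µM — modest fractions of the evoked response);
  scheduled motion artifacts as transient fractional intensity excursions.
  Forward projection to intensities is the exact MBLL relation, so
  forward-then-invert is an identity when noise is off.
- **Drift streams**: mean-one series with a centred deterministic ramp
  (default 0.4 %/h, within the < 0.6 %/h class of a stable instrument) plus
  white (2×10⁻⁴) and 1/f flicker (1×10⁻⁴ fractional rms) components.

## QC metric conventions

- **SNR** uses the sample standard deviation (n−1) of the four A−B repeat
  differences; at n = 4 the population-vs-sample choice shifts results by
  ≈ 1 dB, so the convention matters and is fixed here. Zero spread returns a
  +∞ sentinel; a negative mean difference (states swapped) is an error. The
  simulated two-state protocol draws each channel's calibrated perturbation
  uniformly in 3–4 optical dB (`P_B = P_A/10^{dB/10}`; optical-power ratios
  use 10·log₁₀, the MGV-domain SNR keeps its 20·log₁₀ definition).
- **NEP**: literal evaluation of the per-pixel and √N-summed formulas.
  With these datasheet constants the absolute result is ~29 fW/√Hz at
  695 nm, which does not reproduce the ~5.3 pW/√Hz figure quoted for such
  instruments — the absolute scale of that figure is not recoverable from
  the printed formula, while the 830/695 ratio (695·η₆₉₅)/(830·η₈₃₀) ≈ 1.320
  matches the quoted ratio to 0.3 %. Only the ratio is treated as checkable.
- **Drift triple**: least-squares slope of the percent-of-mean signal
  (≥ 10 min of data required); overlapping Allan deviation
  `σ_y²(τ) = ½⟨(ȳ_{k+1}−ȳ_k)²⟩` on the percent-of-mean signal (raw-unit
  mode available); ±3σ occupancy uses the whole-record standard deviation,
  not a rolling window. The published unitless Allan summary values
  ("0.15 ± 0.16") have no stated normalisation and are not matched.

## Preprocessing choices

- **Motion artifacts**: the named thresholds (STDthresh = 10, AMPthresh = 5,
  tMask = 0.5 s) are public but the operator is not; this package uses a
  Homer-style windowed change detector: a 0.5 s sliding window flags its
  samples when the windowed peak-to-peak excursion exceeds STDthresh × the
  robust (MAD) standard deviation of the sample-to-sample differences, or
  exceeds AMPthresh outright on the normalised-intensity scale; flags dilate
  by tMask each side. Other Homer variants will not mask identical sample
  sets.
- **Rejection rules**: strict thresholds — a channel is rejected when *more
  than* 5 % of samples are contaminated; a session's channel-pair data are
  excluded when *more than* 30 % of channels are bad in at least one
  participant. Both rules are idempotent.
- **Filtering order**: intensities are converted to ΔOD against the baseline
  window (pre-task rest for task runs, the first block for phantoms), masked
  samples are bridged by linear interpolation so their values cannot leak
  through the filter, and the zero-phase order-3 Butterworth band-pass
  (0.01–0.2 Hz) runs on ΔOD. Filtering the raw intensity first would make
  the subsequent logarithm ill-defined once DC is removed. The NEP
  bandwidth (0.09 Hz, from a 0.01–0.1 Hz analysis band) and the filter band
  (0.01–0.2 Hz) are both kept as printed even though they differ.
- **MBLL**: per-sample 2 × 2 solve; condition number of the scaled
  extinction matrix is checked (error above 10⁶). DPF defaults to 6.0 at
  both wavelengths for in-vivo-style processing (ΔHb is then conditional on
  that DPF/L). The blood-phantom runner instead derives per-wavelength DPFs
  from the diffusion model at the phantom's designed baseline
  (`DPF = −(1/ρ)·∂lnR/∂μ_a`), which a phantom study can do because the
  recipe is known; with DPF fixed per wavelength the MBLL linearisation of
  the strongly varying pathlength is the dominant systematic in the
  recovered SO₂ slope.
- **SO₂ estimate**: `SO₂(t) = (HbO₀+ΔHbO)/(tHb₀+ΔHbO+ΔHbR)` against the
  known phantom baseline, clipped to [0, 1] with clip events counted. CW
  data alone cannot give absolute SO₂ without such a baseline assumption.

## Operating points and problem sizes

Emitter levels mirror how the physical instrument is driven: titration and
task runs sit at the forehead operating level (≈ 335 signal ADU), while the
deoxygenation run sets the brightest course point just below full scale
(≈ 3600 ADU), following the dynamic-range procedure of maximising
non-saturating signal — the 695 nm signal falls by ~4.7 orders of magnitude
over a full deoxygenation, so headroom decides whether the endpoint is
resolvable. Default problem sizes: 10 titration points × 3 cycles, 12
reference samples × 6 cycles, 4 SNR repeats over all 52 channels; emitter
powers carry a 5 % spread that source-normalisation removes. These sizes
keep a full rehearsal in the tens of seconds per experiment; all per-sample
physics is identical at larger sizes.

## Known limitations

- The scattering–absorption titration is *intrinsically* slightly nonlinear
  here: over the baseline μ_a range the modelled intensity falls ~51 % and
  the exponential curvature of `R ∝ e^{−ρμ_eff(μ_a)}` caps the MGV%-vs-μ_a
  linear R² at ≈ 0.9874 at 695 nm (0.997 at 830 nm, where the relative μ_a
  swing is smaller) even with the camera noiseless. A physical rig whose
  effective path is shorter than ideal semi-infinite reflectance at 30 mm
  would look more linear. The acceptance suite states the ≥ 0.99 bound and
  the 695 nm run honestly fails it by ~0.003; the square-root-transformed
  high-absorption readout and the SO₂ recovery are unaffected.
- No photon-transport Monte Carlo, layered media, melanin/skin-tone
  absorption, optical PSF, fixed-pattern noise, rolling shutter, or spot
  drift/registration: passing tests show the *processing chain* is
  faithful, not that a physical camera will meet the same numbers.
- Speckle statistics are reduced to their ROI mean; speckle-contrast
  analyses cannot be rehearsed on this twin.
- SNIRF I/O covers the continuous-wave amplitude profile (one data block,
  dataType 1) — enough for round-tripping this instrument's series, not a
  general SNIRF implementation.
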