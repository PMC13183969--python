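"""Forward optics and synthetic experiment generators.

This module supplies everything upstream of the camera: the continuous-wave
diffuse-reflectance forward model that maps phantom optical properties to
relative detected power, recipes for the scattering/absorbing liquid phantoms
(Intralipid + India ink, and a blood-doped variant), and the generators for
the four study designs -- ink titration, blood deoxygenation, a block-design
verbal-fluency task, and long-duration drift streams.

Light propagation uses the semi-infinite extrapolated-boundary CW diffusion
solution (Kienle & Patterson form) with diffusion coefficient
``D = 1/(3 (mu_a + mu_s'))`` and internal-reflection parameter derived from
the refractive index (1.33 for liquid phantoms).  Only *relative* intensity
is ever used downstream.  All generators are bit-for-bit reproducible under a
fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

__all__ = [
    "OpticalMedium",
    "InkTitration",
    "BloodPhantom",
    "VFTDesign",
    "DriftModel",
    "DeoxygenationCourse",
    "VFTResult",
    "HEMOGLOBIN_EXTINCTION_MM_MM",
    "WATER_MUA_MM",
    "INK_SPECTRAL_RATIO",
    "extinction_mm_mM",
    "mueff",
    "kienle_reflectance",
    "diffusion_reflectance",
    "diffusion_dpf",
    "intralipid_musp",
    "intralipid_fraction_for_musp",
    "titration_mua_series",
    "titration_mua_at",
    "baseline_titration",
    "low_absorption_titration",
    "high_absorption_titration",
    "blood_mua",
    "deoxygenation_course",
    "vft_hemodynamics",
    "drift_series",
    "canonical_hrf",
]

# ---------------------------------------------------------------------------
# chromophores and background absorbers
# ---------------------------------------------------------------------------

# Decadic molar extinction coefficients, mm^-1 mM^-1, compiled from the
# standard Prahl (Oregon Medical Laser Center) tabulation (original units
# cm^-1 M^-1, converted by 1e-4).  Linearly interpolated between entries.
HEMOGLOBIN_EXTINCTION_MM_MM: Dict[float, Tuple[float, float]] = {
    # wavelength nm: (HbO2, Hb)
    660.0: (0.0320, 0.3227),
    690.0: (0.0276, 0.2052),
    700.0: (0.0290, 0.1794),
    750.0: (0.0562, 0.1405),
    800.0: (0.0816, 0.0762),
    830.0: (0.0974, 0.0693),
    850.0: (0.1058, 0.0691),
    900.0: (0.1198, 0.0754),
}

# Pure-water absorption, mm^-1 (Hale & Querry scale), at the operating wavelengths.
WATER_MUA_MM: Dict[float, float] = {695.0: 0.0005, 830.0: 0.0029}

# India-ink absorption relative to its value at 695 nm (ink is spectrally
# nearly flat, mildly decreasing towards the NIR).
INK_SPECTRAL_RATIO: Dict[float, float] = {695.0: 1.0, 830.0: 0.85}


def extinction_mm_mM(wavelength_nm: float,
                     table: Mapping[float, Tuple[float, float]] | None = None
                     ) -> Tuple[float, float]:
    """(epsilon_HbO2, epsilon_HbR) in mm^-1 mM^-1, linearly interpolated."""
    table = HEMOGLOBIN_EXTINCTION_MM_MM if table is None else table
    wls = sorted(table)
    if not (wls[0] <= wavelength_nm <= wls[-1]):
        raise KeyError(f"wavelength {wavelength_nm} nm outside extinction table "
                       f"range {wls[0]}-{wls[-1]} nm")
    if wavelength_nm in table:
        return table[wavelength_nm]
    hi = next(w for w in wls if w > wavelength_nm)
    lo = max(w for w in wls if w < wavelength_nm)
    f = (wavelength_nm - lo) / (hi - lo)
    eo = table[lo][0] + f * (table[hi][0] - table[lo][0])
    er = table[lo][1] + f * (table[hi][1] - table[lo][1])
    return (eo, er)


# ---------------------------------------------------------------------------
# optical medium and diffusion forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous turbid medium: per-wavelength mu_a and mu_s' in mm^-1."""

    mua: Mapping[float, float]
    musp: Mapping[float, float]
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        for wl, mua in self.mua.items():
            if mua < 0:
                raise ValueError(f"mu_a must be non-negative at {wl} nm")
            musp = self.musp[wl]
            if musp <= 0:
                raise ValueError(f"mu_s' must be positive at {wl} nm")
            if musp <= mua:
                raise ValueError(
                    f"non-diffusive medium at {wl} nm: mu_s'={musp} <= mu_a={mua}")
            if musp / max(mua, 1e-12) < 10:
                warnings.warn(
                    f"mu_s'/mu_a = {musp / mua:.1f} < 10 at {wl} nm: "
                    "diffusion approximation is marginal", stacklevel=2)


def mueff(mua, musp):
    """Effective attenuation coefficient ``sqrt(3 mu_a (mu_a + mu_s'))`` (mm^-1)."""
    mua = np.asarray(mua, dtype=float)
    return np.sqrt(3.0 * mua * (mua + musp))


def _internal_reflection_A(n: float) -> float:
    # Groenhuis polynomial approximation of the internal-reflection parameter
    rd = -1.440 / n ** 2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1 + rd) / (1 - rd)


def kienle_reflectance(mua, musp: float, rho_mm: float,
                       n_medium: float = 1.33):
    """Semi-infinite CW diffuse reflectance at separation ``rho_mm``.

    Extrapolated-boundary solution with an isotropic source buried one
    transport mean free path deep and its mirror image above the extrapolated
    boundary.  Returns relative detected power (arbitrary units); vectorised
    over ``mua``.  Strictly decreasing in both ``mua`` and ``rho``.
    """
    mua = np.asarray(mua, dtype=float)
    if rho_mm <= 0:
        raise ValueError("rho must be positive")
    if np.any(mua < 0):
        raise ValueError("mu_a must be non-negative")
    if np.any(musp <= mua):
        raise ValueError("non-diffusive medium: mu_s' must exceed mu_a")
    mut = mua + musp
    D = 1.0 / (3.0 * mut)
    ueff = np.sqrt(mua / D)
    z0 = 1.0 / mut
    zb = 2.0 * _internal_reflection_A(n_medium) * D
    r1 = np.sqrt(rho_mm ** 2 + z0 ** 2)
    r2 = np.sqrt(rho_mm ** 2 + (z0 + 2 * zb) ** 2)
    term1 = z0 * (ueff + 1.0 / r1) * np.exp(-ueff * r1) / r1 ** 2
    term2 = (z0 + 2 * zb) * (ueff + 1.0 / r2) * np.exp(-ueff * r2) / r2 ** 2
    return (term1 + term2) / (4.0 * np.pi)


def diffusion_reflectance(medium: OpticalMedium, rho_mm: float) -> Dict[float, float]:
    """Per-wavelength relative detected power for a medium at separation rho."""
    return {wl: float(kienle_reflectance(medium.mua[wl], medium.musp[wl], rho_mm,
                                         medium.refractive_index))
            for wl in medium.mua}


def diffusion_dpf(mua: float, musp: float, rho_mm: float,
                  n_medium: float = 1.33) -> float:
    """Differential pathlength factor implied by the diffusion model.

    ``DPF = -(1/rho) d ln R / d mu_a`` evaluated by central differences at the
    operating point; used by the phantom pipelines where the recipe is known.
    """
    h = 1e-6
    lo = math.log(float(kienle_reflectance(mua - h, musp, rho_mm, n_medium)))
    hi = math.log(float(kienle_reflectance(mua + h, musp, rho_mm, n_medium)))
    return -(hi - lo) / (2 * h) / rho_mm


# ---------------------------------------------------------------------------
# Intralipid scattering (van Staveren empirical model)
# ---------------------------------------------------------------------------

def intralipid_musp(lipid_fraction: float, wavelength_nm: float) -> float:
    """Reduced scattering of an Intralipid dilution, mm^-1.

    van Staveren empirical model for Intralipid-10% (valid 400-1100 nm):
    ``mu_s = 16 lambda_um^-2.4`` mm^-1 at full strength (10% lipid) and
    anisotropy ``g = 1.1 - 0.58 lambda_um``; both scale linearly with the
    lipid volume fraction.
    """
    if lipid_fraction < 0:
        raise ValueError("lipid fraction must be non-negative")
    if not (400 <= wavelength_nm <= 1100):
        raise ValueError("wavelength outside the 400-1100 nm empirical validity range")
    lam_um = wavelength_nm / 1000.0
    mus_full = 16.0 * lam_um ** -2.4  # Intralipid-10% stock, mm^-1
    g = 1.1 - 0.58 * lam_um
    return (lipid_fraction / 0.10) * mus_full * (1.0 - g)


def intralipid_fraction_for_musp(target_musp: float, wavelength_nm: float) -> float:
    """Inverse query: lipid volume fraction achieving ``target_musp`` at ``wavelength``."""
    if target_musp < 0:
        raise ValueError("target mu_s' must be non-negative")
    unit = intralipid_musp(0.10, wavelength_nm)  # mu_s' of 10% lipid
    return 0.10 * target_musp / unit


# ---------------------------------------------------------------------------
# ink titration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InkTitration:
    """Stepwise India-ink addition into a stirred Intralipid phantom.

    ``mua_k = base + k * increment_volume_ul * ink_specific_absorption`` at
    695 nm for steps ``k = 0..n_steps``.  ``ink_specific_absorption`` is the
    mu_a gained per microlitre of ink in the phantom volume.
    """

    base_mua: float
    ink_specific_absorption: float  # mm^-1 per uL
    n_steps: int
    increment_volume_ul: float = 2.0
    stir_settle: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.n_steps >= 1 and self.ink_specific_absorption * self.increment_volume_ul <= 0:
            raise ValueError("mu_a series must be strictly increasing")


def titration_mua_series(tit: InkTitration) -> np.ndarray:
    """Ordered mu_a values (mm^-1, at 695 nm), length ``n_steps + 1``."""
    k = np.arange(tit.n_steps + 1)
    return tit.base_mua + k * tit.increment_volume_ul * tit.ink_specific_absorption


def titration_mua_at(mua_695: np.ndarray, wavelength_nm: float) -> np.ndarray:
    """Translate a 695 nm titration mu_a series to another wavelength.

    The non-water part (ink + residual Intralipid absorption) is scaled by the
    ink spectral ratio; the water background is swapped for its value at the
    target wavelength.
    """
    ratio = INK_SPECTRAL_RATIO[wavelength_nm]
    w0, w1 = WATER_MUA_MM[695.0], WATER_MUA_MM[wavelength_nm]
    return w1 + (np.asarray(mua_695, dtype=float) - w0) * ratio


def _preset(base: float, end: float, n_steps: int) -> InkTitration:
    spec_abs = (end - base) / (n_steps * 2.0)
    return InkTitration(base_mua=base, ink_specific_absorption=spec_abs, n_steps=n_steps)


def baseline_titration(n_steps: int = 9) -> InkTitration:
    """Baseline-range preset: mu_a 0.00899 -> 0.01100 mm^-1 at 695 nm."""
    return _preset(0.00899, 0.01100, n_steps)


def low_absorption_titration(n_steps: int = 9) -> InkTitration:
    """Low-absorption preset: mu_a 0.01192 -> 0.01254 mm^-1 at 695 nm."""
    return _preset(0.01192, 0.01254, n_steps)


def high_absorption_titration(n_steps: int = 9) -> InkTitration:
    """High-absorption preset: mu_a 0.03366 -> 0.04639 mm^-1 at 695 nm."""
    return _preset(0.03366, 0.04639, n_steps)


# ---------------------------------------------------------------------------
# blood-doped phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BloodPhantom:
    """Intralipid + whole-blood phantom for controlled SO2 experiments.

    Defaults: 5% blood by volume; whole blood at ~2.3 mM haemoglobin gives a
    mixture tHb of 0.115 mM; Intralipid adjusted to mu_s' = 2.3 mm^-1 at
    695 nm (the 830 nm value follows the van Staveren wavelength scaling);
    water as the only background absorber.
    """

    blood_volume_fraction: float = 0.05
    total_hemoglobin_mM: float = 0.115  # of the mixture
    musp: Mapping[float, float] = field(default_factory=lambda: {
        695.0: 2.3,
        830.0: round(2.3 * intralipid_musp(0.02, 830.0) / intralipid_musp(0.02, 695.0), 4),
    })
    background_mua: Mapping[float, float] = field(
        default_factory=lambda: dict(WATER_MUA_MM))
    extinction: Mapping[float, Tuple[float, float]] | None = None

    def eps(self, wavelength_nm: float) -> Tuple[float, float]:
        return extinction_mm_mM(wavelength_nm, self.extinction)


def blood_mua(ph: BloodPhantom, so2: float, wavelength_nm: float) -> float:
    """mu_a (mm^-1) of the phantom at haemoglobin saturation ``so2``.

    ``mu_a = ln(10) tHb (so2 eps_HbO + (1 - so2) eps_HbR) + background``.
    """
    if not (0.0 <= so2 <= 1.0):
        raise ValueError("SO2 must lie in [0, 1]")
    eo, er = ph.eps(wavelength_nm)
    hb = math.log(10.0) * ph.total_hemoglobin_mM * (so2 * eo + (1 - so2) * er)
    return hb + ph.background_mua[wavelength_nm]


@dataclass(frozen=True)
class DeoxygenationCourse:
    """A monotone SO2(t) course plus its periodic reference samples."""

    times_s: np.ndarray
    so2: np.ndarray
    reference_times_s: np.ndarray
    reference_so2: np.ndarray

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times_s, self.so2))


def deoxygenation_course(duration_s: float = 600.0, n_reference_samples: int = 12,
                         fs_hz: float = 5.0, so2_end: float = 0.0,
                         midpoint_frac: float = 0.5, steepness: float = 0.08,
                         analyzer_noise_sd: float = 0.0,
                         seed: Optional[int] = None) -> DeoxygenationCourse:
    """Sigmoidal 100% -> ``so2_end`` deoxygenation with reference blood-gas samples.

    The logistic in normalised time is rescaled to hit 1.0 exactly at t = 0
    and ``so2_end`` exactly at t = duration, so the course is monotone
    non-increasing pointwise.  ``so2_end = 1.0`` (no depleting agent) gives a
    constant course.  Reference samples are exact course readings at evenly
    spaced times, optionally perturbed by analyser noise.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(0.0, duration_s + 0.5 / fs_hz, 1.0 / fs_hz)
    x = t / duration_s

    def logistic(u):
        return 1.0 / (1.0 + np.exp((u - midpoint_frac) / steepness))

    l0, l1 = logistic(0.0), logistic(1.0)
    shape = (logistic(x) - l1) / (l0 - l1)
    so2 = so2_end + (1.0 - so2_end) * shape
    tref = np.linspace(0.0, duration_s, n_reference_samples)
    ref = np.interp(tref, t, so2)
    if analyzer_noise_sd > 0:
        rng = np.random.default_rng(seed)
        ref = np.clip(ref + rng.normal(0, analyzer_noise_sd, ref.shape), 0.0, 1.0)
    return DeoxygenationCourse(times_s=t, so2=so2,
                               reference_times_s=tref, reference_so2=ref)


# ---------------------------------------------------------------------------
# block-design task hemodynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VFTDesign:
    """Verbal-fluency block design: 30 s rest, 60 s task, 60 s recovery.

    Response amplitudes are concentration changes in mM (typical evoked
    prefrontal responses are of order 1 uM HbO with a smaller opposite-signed
    HbR change).  Physiological oscillations (cardiac ~1 Hz, respiratory
    ~0.3 Hz, Mayer waves ~0.1 Hz) are added in the concentration domain;
    motion artifacts are injected as transient intensity excursions.
    """

    pre_rest_s: float = 30.0
    task_s: float = 60.0
    post_rest_s: float = 60.0
    hbo_peak_mM: float = 0.001
    hbr_peak_mM: float = -0.0003
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    cardiac_amp_mM: float = 0.0002
    cardiac_hz: float = 1.1
    respiratory_amp_mM: float = 0.0001
    respiratory_hz: float = 0.3
    mayer_amp_mM: float = 0.0001
    mayer_hz: float = 0.1
    # (onset_s, duration_s, fractional intensity amplitude)
    motion_events: Tuple[Tuple[float, float, float], ...] = ((100.0, 0.6, 0.15),)

    def __post_init__(self) -> None:
        if min(self.pre_rest_s, self.task_s, self.post_rest_s) <= 0:
            raise ValueError("block durations must be positive")

    @property
    def duration_s(self) -> float:
        return self.pre_rest_s + self.task_s + self.post_rest_s


def canonical_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Double-gamma haemodynamic response, unit peak amplitude."""
    t = np.asarray(t, dtype=float)

    def gamma_pdf(x, shape):
        x = np.maximum(x, 0.0)
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp((shape - 1) * np.log(x[pos]) - x[pos] - gammaln(shape))
        return out

    h = gamma_pdf(t, peak_s) - undershoot_ratio * gamma_pdf(t, undershoot_s)
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass(frozen=True)
class VFTResult:
    """Ground-truth concentration courses plus contaminated optical intensities."""

    times_s: np.ndarray
    hbo_true_mM: np.ndarray  # noiseless evoked response
    hbr_true_mM: np.ndarray
    # per wavelength: relative intensity I/I0, shape (n_channels, n_samples)
    intensities: Dict[float, np.ndarray]
    motion_truth: np.ndarray  # boolean, samples carrying injected artifacts
    design: VFTDesign
    dpf: Mapping[float, float]
    pathlength_mm: float


def vft_hemodynamics(design: VFTDesign, fs_hz: float, seed,
                     n_channels: int = 1,
                     wavelengths: Sequence[float] = (695.0, 830.0),
                     dpf: Mapping[float, float] | None = None,
                     pathlength_mm: float = 30.0) -> VFTResult:
    """Generate evoked Hb courses and forward-project them to intensities.

    The task boxcar is convolved with the canonical double-gamma kernel and
    scaled to the design's peak amplitudes; physiological sinusoids (random
    phases) and scheduled motion artifacts contaminate the measured
    intensities but not the returned ground truth.  The forward projection is
    the modified Beer-Lambert relation
    ``I = I0 10^-(eps_HbO dHbO + eps_HbR dHbR) L DPF``.
    """
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    dpf = {wl: 6.0 for wl in wavelengths} if dpf is None else dict(dpf)
    n = int(round(design.duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    boxcar = ((t >= design.pre_rest_s) & (t < design.pre_rest_s + design.task_s)).astype(float)
    kernel = canonical_hrf(np.arange(0, 32.0, 1.0 / fs_hz), design.hrf_peak_s,
                           design.hrf_undershoot_s, design.hrf_undershoot_ratio)
    resp = np.convolve(boxcar, kernel)[:n]
    peak = resp.max()
    resp = resp / peak if peak > 0 else resp
    hbo = design.hbo_peak_mM * resp
    hbr = design.hbr_peak_mM * resp
    motion = np.zeros(n, dtype=bool)
    for onset, dur, _amp in design.motion_events:
        motion |= (t >= onset) & (t < onset + dur)

    intensities: Dict[float, np.ndarray] = {}
    for wl in wavelengths:
        eo, er = extinction_mm_mM(wl)
        eff_l = pathlength_mm * dpf[wl]
        chans = np.empty((n_channels, n))
        for c in range(n_channels):
            phases = rng.uniform(0, 2 * np.pi, size=3)
            physio = (design.cardiac_amp_mM * np.sin(2 * np.pi * design.cardiac_hz * t + phases[0])
                      + design.respiratory_amp_mM * np.sin(2 * np.pi * design.respiratory_hz * t + phases[1])
                      + design.mayer_amp_mM * np.sin(2 * np.pi * design.mayer_hz * t + phases[2]))
            # physiological oscillations ride mostly on HbO with a smaller HbR share
            dod = (eo * (hbo + physio) + er * (hbr + 0.25 * physio)) * eff_l
            intensity = 10.0 ** (-dod)
            for onset, dur, amp in design.motion_events:
                idx = (t >= onset) & (t < onset + dur)
                intensity[idx] *= 1.0 + amp * rng.choice([-1.0, 1.0])
            chans[c] = intensity
        intensities[wl] = chans
    return VFTResult(times_s=t, hbo_true_mM=hbo, hbr_true_mM=hbr,
                     intensities=intensities, motion_truth=motion,
                     design=design, dpf=dpf, pathlength_mm=pathlength_mm)


# ---------------------------------------------------------------------------
# instrument drift streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftModel:
    """Deterministic linear trend plus stochastic flicker and white components.

    Amplitudes are fractions of the mean signal; the generated stream is
    mean-one with the ramp centred so a least-squares fit recovers
    ``linear_rate_pct_per_h`` exactly in the noiseless case.
    """

    linear_rate_pct_per_h: float = 0.4
    white_sigma_frac: float = 2e-4
    flicker_sigma_frac: float = 1e-4
    temperature_label: str = "25C"


def drift_series(model: DriftModel, duration_s: float, fs_hz: float,
                 seed) -> np.ndarray:
    """Mean-one intensity stream with the configured drift and noise."""
    if duration_s <= 0 or fs_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t_h = np.arange(n) / fs_hz / 3600.0
    stream = 1.0 + (model.linear_rate_pct_per_h / 100.0) * (t_h - t_h.mean())
    if model.white_sigma_frac > 0:
        stream = stream + rng.normal(0, model.white_sigma_frac, n)
    if model.flicker_sigma_frac > 0:
        # shape white noise to 1/f by spectral filtering
        white = rng.normal(0, 1.0, n)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
        shaping = np.ones_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:] / freqs[1])
        shaping[0] = 0.0
        flicker = np.fft.irfft(spec * shaping, n)
        flicker *= model.flicker_sigma_frac / max(flicker.std(), 1e-300)
        stream = stream + flicker
    return stream
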