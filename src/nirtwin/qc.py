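"""Instrument characterisation: SNR, noise-equivalent power, dynamic range, drift.

The two-state SNR follows the differential protocol of the medical-electrical
standard for NIRS equipment: a calibrated 3-4 dB optical perturbation against
a > 60 dB loss baseline creates states A and B, the transition is repeated
four times per channel, and

    SNR(dB) = 20 log10( mean(MGV_A - MGV_B) / sd(MGV_A - MGV_B) )

with the sample standard deviation (n-1).  NEP and dynamic-optical-range are
literal evaluations of the corresponding photometric relations; the drift
triple comprises the least-squares linear drift rate (%/h), the overlapping
Allan deviation of the percent-of-mean signal, and the percentage of time the
signal spends within +/- 3 sigma of its mean.

A note on the theoretical NEP: evaluating the per-pixel formula with this
sensor's datasheet constants and summing over the N ~ 3.3e4 spot pixels gives
~29 fW/sqrt(Hz) at 695 nm; published figures for comparable instruments quote
~5.3 pW/sqrt(Hz), an absolute scale the printed formula does not reproduce,
while the 830/695 nm ratio (~1.32) agrees to better than 0.5%.  This
implementation evaluates the formulas literally and treats only the ratio as
checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .optode import ChannelMap, TDMSchedule
from .sensor import (PLANCK_H, SPEED_OF_LIGHT, SensorSpec, SpotLayout,
                     power_for_electrons, simulate_stream)
from .extraction import demultiplex, rois_from_layout

__all__ = [
    "PhysicalConstants",
    "TwoStateMeasurement",
    "NEPParams",
    "DriftMetrics",
    "snr_two_state",
    "nep_theoretical",
    "nep_actual",
    "dynamic_optical_range",
    "linear_drift_rate",
    "allan_deviation",
    "sigma3_occupancy",
    "drift_metrics",
    "run_snr_protocol",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 exact values."""

    h: float = PLANCK_H
    c: float = SPEED_OF_LIGHT


@dataclass(frozen=True)
class TwoStateMeasurement:
    """Paired state-mean MGVs over repeats of an A->B transition."""

    mgv_a: np.ndarray
    mgv_b: np.ndarray
    channel_id: int = 0
    wavelength_nm: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.mgv_a, dtype=float)
        b = np.asarray(self.mgv_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("state means must be equal-length 1-D arrays")
        if a.size < 2:
            raise ValueError("need at least 2 repeats for a defined standard deviation")
        object.__setattr__(self, "mgv_a", a)
        object.__setattr__(self, "mgv_b", b)

    @property
    def differences(self) -> np.ndarray:
        return self.mgv_a - self.mgv_b


def snr_two_state(m: TwoStateMeasurement) -> float:
    """Two-state differential SNR in dB; +inf sentinel for zero repeat spread."""
    d = m.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if mean < 0:
        raise ValueError("negative mean state difference: states A and B appear swapped")
    if sd == 0.0:
        return math.inf
    return 20.0 * math.log10(mean / sd)


@dataclass(frozen=True)
class NEPParams:
    """Constants entering the NEP formulas for one wavelength."""

    wavelength_nm: float
    eta: float
    read_noise_e: float = 3.57
    exposure_s: float = 0.025
    bandwidth_hz: float = 0.09  # final analysis bandwidth 0.01-0.1 Hz
    n_pixels: int = 32686  # pixels summed over the ~102-px-radius spot
    conversion_gain: float = 2.33

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "eta", "read_noise_e", "exposure_s",
                     "bandwidth_hz", "n_pixels", "conversion_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def nep_theoretical(p: NEPParams, k: PhysicalConstants = PhysicalConstants()
                    ) -> Tuple[float, float]:
    """(NEP_pix, NEP_sum) in W/sqrt(Hz).

    ``NEP_pix = Q h c / (lambda t eta sqrt(BW))`` and
    ``NEP_sum ~= sqrt(N) NEP_pix`` for N incoherently summed pixels.
    """
    lam_m = p.wavelength_nm * 1e-9
    nep_pix = p.read_noise_e * k.h * k.c / (lam_m * p.exposure_s * p.eta
                                            * math.sqrt(p.bandwidth_hz))
    return nep_pix, math.sqrt(p.n_pixels) * nep_pix


def nep_actual(mgv_snr1_adu: float, p: NEPParams,
               k: PhysicalConstants = PhysicalConstants()) -> float:
    """Measured NEP from the MGV at which SNR = 1.

    ``Q_SNR=1 = N MGV CG`` electrons over the spot, then the same photometric
    relation as the theoretical form.
    """
    if mgv_snr1_adu < 0:
        raise ValueError("MGV at SNR=1 must be non-negative")
    q_snr1 = p.n_pixels * mgv_snr1_adu * p.conversion_gain
    lam_m = p.wavelength_nm * 1e-9
    return q_snr1 * k.h * k.c / (lam_m * p.exposure_s * p.eta
                                 * math.sqrt(p.bandwidth_hz))


def dynamic_optical_range(mgv_max: float, mgv_min: float) -> float:
    """``DOR = 10 log10(MGV_max / MGV_min)`` in dB."""
    if mgv_min <= 0:
        raise ValueError("MGV_min must be positive")
    if mgv_max < mgv_min:
        raise ValueError("MGV_max must be >= MGV_min")
    return 10.0 * math.log10(mgv_max / mgv_min)


def _percent_of_mean(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    mean = series.mean()
    if mean == 0:
        raise ValueError("series mean is zero; percent-of-mean undefined")
    return 100.0 * series / mean


def linear_drift_rate(series: np.ndarray, fs_hz: float) -> float:
    """Least-squares slope of the percent-of-mean signal, in %/h.

    Requires at least 10 minutes of data for a meaningful trend estimate.
    """
    series = np.asarray(series, dtype=float)
    if series.size / fs_hz < 600.0:
        raise ValueError("need at least 10 minutes of data for a drift estimate")
    pct = _percent_of_mean(series)
    t_h = np.arange(series.size) / fs_hz / 3600.0
    slope, _ = np.polyfit(t_h, pct, 1)
    return float(slope)


def allan_deviation(series: np.ndarray, fs_hz: float,
                    taus_s: Sequence[float],
                    normalize: str = "percent") -> Dict[float, float]:
    """Overlapping Allan deviation per tau.

    ``sigma_y(tau)^2 = 1/2 < (ybar_{k+1} - ybar_k)^2 >`` over overlapping
    pairs of adjacent tau-long averages.  With ``normalize="percent"``
    (default) the input is first expressed as percent of its mean, matching
    the drift-characterisation convention; ``normalize="none"`` operates on
    the raw series.  Each tau must not exceed a third of the record length.
    """
    series = np.asarray(series, dtype=float)
    duration = series.size / fs_hz
    taus = [tau for tau in taus_s if tau <= duration / 3.0 and tau >= 1.0 / fs_hz]
    if not taus:
        raise ValueError("tau grid empty after feasibility filtering")
    if normalize == "percent":
        pct = _percent_of_mean(series)
    elif normalize == "none":
        pct = series
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    out: Dict[float, float] = {}
    csum = np.concatenate([[0.0], np.cumsum(pct)])
    for tau in taus:
        m = max(1, int(round(tau * fs_hz)))
        if 2 * m > series.size:
            continue
        means = (csum[m:] - csum[:-m]) / m  # overlapping m-sample averages
        diffs = means[m:] - means[:-m]
        out[tau] = float(np.sqrt(0.5 * np.mean(diffs ** 2)))
    return out


def sigma3_occupancy(series: np.ndarray) -> float:
    """Percent of samples within mean +/- 3 sd (whole-record sd)."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples")
    sd = series.std(ddof=1)
    if sd == 0:
        return 100.0
    within = np.abs(series - series.mean()) <= 3.0 * sd
    return 100.0 * float(within.mean())


@dataclass(frozen=True)
class DriftMetrics:
    linear_rate_pct_per_h: float
    allan_deviation: Dict[float, float]
    sigma3_occupancy_pct: float


def drift_metrics(series: np.ndarray, fs_hz: float,
                  taus_s: Optional[Sequence[float]] = None) -> DriftMetrics:
    """The stability triple for one channel's intensity record."""
    if taus_s is None:
        duration = len(series) / fs_hz
        taus_s = np.logspace(np.log10(1.0 / fs_hz),
                             np.log10(duration / 3.0), 20)
    return DriftMetrics(
        linear_rate_pct_per_h=linear_drift_rate(series, fs_hz),
        allan_deviation=allan_deviation(series, fs_hz, taus_s),
        sigma3_occupancy_pct=sigma3_occupancy(series),
    )


def run_snr_protocol(schedule: TDMSchedule, cmap: ChannelMap, layout: SpotLayout,
                     sensor: SensorSpec, seed,
                     state_a_mgv: float = 335.0,
                     perturbation_db: Tuple[float, float] = (3.0, 4.0),
                     repeats: int = 4,
                     wavelengths: Sequence[float] = (695.0, 830.0)
                     ) -> Dict[Tuple[int, float], float]:
    """Simulated two-state differential SNR protocol, all channels.

    State A drives every channel at the optical power producing
    ``state_a_mgv`` signal ADU; state B attenuates it by a calibrated
    perturbation drawn uniformly in ``perturbation_db`` (optical-power dB,
    ``P_B = P_A / 10^(dB/10)``), fixed per channel across the ``repeats``
    A/B transitions.  Returns the differential SNR per (channel, wavelength).
    """
    rng = np.random.default_rng(seed)
    n_px = layout.n_pixels(next(iter(layout.spots)))
    state_powers: Dict[Tuple[int, float], Tuple[float, float]] = {}
    for ch in cmap.channels:
        for wl in wavelengths:
            mean_e = state_a_mgv * sensor.conversion_gain  # per pixel
            p_a = power_for_electrons(mean_e, wl, sensor, n_pixels=n_px)
            db = rng.uniform(*perturbation_db)
            state_powers[(ch.channel_id, wl)] = (p_a, p_a / 10 ** (db / 10.0))

    mgvs: Dict[Tuple[int, float], Dict[str, list]] = {
        key: {"A": [], "B": []} for key in state_powers}
    for _rep in range(repeats):
        for state, idx in (("A", 0), ("B", 1)):
            courses = {key: np.array([powers[idx]])
                       for key, powers in state_powers.items()}
            frames = simulate_stream(schedule, cmap, courses, sensor, layout, rng)
            series = demultiplex(frames, schedule, cmap, rois_from_layout(layout),
                                 sensor=sensor)
            for key in state_powers:
                mgvs[key][state].append(series[key].values[0])

    out: Dict[Tuple[int, float], float] = {}
    for (cid, wl), rec in mgvs.items():
        m = TwoStateMeasurement(np.array(rec["A"]), np.array(rec["B"]),
                                channel_id=cid, wavelength_nm=wl)
        out[(cid, wl)] = snr_two_state(m)
    return out
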