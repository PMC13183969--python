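"""End-to-end experiment runners: phantom and task protocols through the twin.

Each runner wires the full chain -- forward optics, TDM frame simulation,
ROI extraction, preprocessing -- for one validation experiment, mirroring how
the physical instrument is operated:

* ink titration (absorption-sensitivity curves, with optional square-root
  variance stabilisation for the high-absorption regime),
* blood-phantom deoxygenation (saturation tracking against blood-gas
  reference samples),
* verbal-fluency block design (task hemodynamics through the preprocessing
  pipeline),
* long-duration drift characterisation and the two-state SNR protocol
  (in :mod:`nirtwin.qc`).

Problem sizes (cycles per step, reference-sample counts) are configurable;
the defaults keep a full run in the tens of seconds while leaving the
per-sample physics untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Set, Tuple

import numpy as np

from . import optode, phantoms, pipeline, qc
from .extraction import demultiplex, normalize_by_source, rois_from_layout
from .optode import ChannelMap, OptodeGrid, TDMSchedule
from .phantoms import (BloodPhantom, DeoxygenationCourse, DriftModel,
                       InkTitration, VFTDesign, blood_mua, deoxygenation_course,
                       diffusion_dpf, drift_series, kienle_reflectance,
                       titration_mua_at, titration_mua_series, vft_hemodynamics)
from .sensor import (SensorSpec, SpotLayout, default_layout, power_for_electrons,
                     simulate_stream)

__all__ = [
    "Rig",
    "default_rig",
    "experiment_sensor",
    "TitrationResult",
    "run_titration_experiment",
    "DeoxygenationResult",
    "run_deoxygenation_experiment",
    "VFTRunResult",
    "run_vft_experiment",
    "run_drift_experiment",
]

WAVELENGTHS = (695.0, 830.0)

# mu_s' of the standard phantom recipe (2.3 mm^-1 at 695 nm, van Staveren
# wavelength scaling for the same lipid fraction at 830 nm)
PHANTOM_MUSP = {
    695.0: 2.3,
    830.0: round(2.3 * phantoms.intralipid_musp(0.02, 830.0)
                 / phantoms.intralipid_musp(0.02, 695.0), 4),
}


def experiment_sensor(**overrides) -> SensorSpec:
    """Sensor configuration used for experiment runs: datasheet constants
    plus a 100-ADU camera pedestal so read noise is never clipped at zero."""
    params = dict(bias_adu=100.0)
    params.update(overrides)
    return SensorSpec(**params)


@dataclass(frozen=True)
class Rig:
    """A fully assembled instrument: geometry, schedule, optics, camera."""

    grid: OptodeGrid
    cmap: ChannelMap
    schedule: TDMSchedule
    layout: SpotLayout
    sensor: SensorSpec
    source_spec: "object" = None

    @property
    def rho_mm(self) -> float:
        return self.grid.pitch_mm

    @property
    def fs_hz(self) -> float:
        return self.schedule.sampling_rate_hz


def default_rig(rows: int = 3, cols: int = 11, pitch_mm: float = 30.0,
                n_groups: int = 4, on_ms: float = 25.0, off_ms: float = 25.0,
                sensor: Optional[SensorSpec] = None,
                spot_radius_px: int = 102) -> Rig:
    """The standard 3x11, 52-channel instrument at 5 Hz."""
    grid = optode.build_grid(rows, cols, pitch_mm)
    cmap = optode.enumerate_channels(grid)
    schedule = optode.build_tdm_schedule(grid, n_groups, on_ms, off_ms)
    sensor = experiment_sensor() if sensor is None else sensor
    layout = default_layout(grid, sensor, radius_px=spot_radius_px)
    return Rig(grid=grid, cmap=cmap, schedule=schedule, layout=layout, sensor=sensor)


def _emitter_powers(rig: Rig, rng: np.random.Generator,
                    spread_frac: float) -> Dict[int, float]:
    """Per-source emitted power (mW), with realistic emitter-to-emitter spread."""
    base = 4.0
    n = rig.grid.n_sources
    if spread_frac > 0:
        factors = rng.normal(1.0, spread_frac, n)
    else:
        factors = np.ones(n)
    return {sid: base * float(f) for sid, f in zip(range(1, n + 1), factors)}


def _extract_course(rig: Rig, courses: Mapping[Tuple[int, float], np.ndarray],
                    rng: np.random.Generator, chunk_cycles: int = 25
                    ) -> Dict[Tuple[int, float], np.ndarray]:
    """Simulate a power course through the camera in chunks of cycles.

    Frames are extracted and discarded chunk-by-chunk so memory stays flat
    regardless of course length.
    """
    rois = rois_from_layout(rig.layout)
    n_cycles = len(next(iter(courses.values())))
    out = {key: np.empty(n_cycles) for key in courses}
    for start in range(0, n_cycles, chunk_cycles):
        stop = min(start + chunk_cycles, n_cycles)
        chunk = {key: np.asarray(v)[start:stop] for key, v in courses.items()}
        frames = simulate_stream(rig.schedule, rig.cmap, chunk, rig.sensor,
                                 rig.layout, rng)
        series = demultiplex(frames, rig.schedule, rig.cmap, rois,
                             sensor=rig.sensor)
        for key in courses:
            out[key][start:stop] = series[key].values
    return out


def _channel_block_means(rig: Rig, powers_per_step, n_cycles: int,
                         rng: np.random.Generator,
                         source_powers: Mapping[int, float]
                         ) -> Dict[Tuple[int, float], np.ndarray]:
    """Simulate constant-power blocks and return per-channel block-mean values.

    ``powers_per_step`` maps (channel_id, wavelength) -> array over steps of
    detected power (W) at nominal emitter power; the actual power is scaled
    by the channel's emitter factor, which normalisation then removes.
    """
    n_steps = len(next(iter(powers_per_step.values())))
    chan = {ch.channel_id: ch for ch in rig.cmap.channels}
    rois = rois_from_layout(rig.layout)
    out = {key: np.empty(n_steps) for key in powers_per_step}
    for step in range(n_steps):
        courses = {}
        for (cid, wl), pw in powers_per_step.items():
            factor = source_powers[chan[cid].source_id] / 4.0
            courses[(cid, wl)] = np.full(n_cycles, pw[step] * factor)
        frames = simulate_stream(rig.schedule, rig.cmap, courses, rig.sensor,
                                 rig.layout, rng)
        series = demultiplex(frames, rig.schedule, rig.cmap, rois, sensor=rig.sensor)
        series = normalize_by_source(series, rig.cmap, source_powers)
        for key in powers_per_step:
            out[key][step] = float(np.nanmean(series[key].values))
    return out


# ---------------------------------------------------------------------------
# ink titration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationResult:
    mua: Dict[float, np.ndarray]  # per wavelength, mm^-1
    signal: Dict[float, np.ndarray]  # pooled normalised signal per step
    mgv_percent: Dict[float, np.ndarray]  # 100 (S - S0) / S0
    r2_percent: Dict[float, float]
    r2_sqrt: Dict[float, float]
    per_channel: Dict[Tuple[int, float], np.ndarray]

    @property
    def min_r2_percent(self) -> float:
        return min(self.r2_percent.values())

    @property
    def min_r2_sqrt(self) -> float:
        return min(self.r2_sqrt.values())


def run_titration_experiment(tit: InkTitration, rig: Optional[Rig] = None,
                             seed: int = 0, cycles_per_step: int = 3,
                             operating_mgv: float = 335.0,
                             emitter_spread_frac: float = 0.05
                             ) -> TitrationResult:
    """Full ink-titration chain: diffusion optics -> frames -> MGV regression.

    The emitter level is set so the first (lowest-absorption) step produces
    ``operating_mgv`` signal ADU -- the level observed on a forehead at 30 mm
    separation.  Signals are normalised by emitter power, pooled across
    channels, converted to percent change against the first step, and
    regressed on mu_a per wavelength; the square-root-transformed normalised
    signal is regressed likewise for the variance-stabilised readout.
    """
    rig = default_rig() if rig is None else rig
    rng = np.random.default_rng(seed)
    mua695 = titration_mua_series(tit)
    mua = {wl: titration_mua_at(mua695, wl) for wl in WAVELENGTHS}
    n_px = rig.layout.n_pixels(next(iter(rig.layout.spots)))

    powers_per_step: Dict[Tuple[int, float], np.ndarray] = {}
    for wl in WAVELENGTHS:
        refl = kienle_reflectance(mua[wl], PHANTOM_MUSP[wl], rig.rho_mm)
        p0 = power_for_electrons(operating_mgv * rig.sensor.conversion_gain,
                                 wl, rig.sensor, n_pixels=n_px)
        course = p0 * refl / refl[0]
        for ch in rig.cmap.channels:
            powers_per_step[(ch.channel_id, wl)] = course

    source_powers = _emitter_powers(rig, rng, emitter_spread_frac)
    means = _channel_block_means(rig, powers_per_step, cycles_per_step, rng,
                                 source_powers)

    signal, pct, r2p, r2s = {}, {}, {}, {}
    per_channel: Dict[Tuple[int, float], np.ndarray] = {}
    for wl in WAVELENGTHS:
        mat = np.vstack([means[(ch.channel_id, wl)] for ch in rig.cmap.channels])
        for ch in rig.cmap.channels:
            per_channel[(ch.channel_id, wl)] = means[(ch.channel_id, wl)]
        pooled = mat.mean(axis=0)
        signal[wl] = pooled
        pct[wl] = 100.0 * (pooled - pooled[0]) / pooled[0]
        _, _, r2p[wl] = pipeline.linear_fit_r2(mua[wl], pct[wl])
        _, _, r2s[wl] = pipeline.linear_fit_r2(
            mua[wl], pipeline.sqrt_transform(pooled / pooled[0]))
    return TitrationResult(mua=mua, signal=signal, mgv_percent=pct,
                           r2_percent=r2p, r2_sqrt=r2s, per_channel=per_channel)


# ---------------------------------------------------------------------------
# blood-phantom deoxygenation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeoxygenationResult:
    reference_so2: np.ndarray
    recovered_dso2: np.ndarray
    recovered_so2: np.ndarray
    hbo_mM: np.ndarray
    hbr_mM: np.ndarray
    r2: float
    slope: float
    dpf: Dict[float, float]
    course: DeoxygenationCourse


def run_deoxygenation_experiment(phantom: Optional[BloodPhantom] = None,
                                 rig: Optional[Rig] = None, seed: int = 0,
                                 duration_s: float = 600.0,
                                 n_reference_samples: int = 12,
                                 cycles_per_sample: int = 6,
                                 operating_mgv: float = 3600.0,
                                 course: Optional[DeoxygenationCourse] = None
                                 ) -> DeoxygenationResult:
    """Simulated 100% -> 0% SO2 course recovered through the MBLL pipeline.

    The camera records a block of cycles around each blood-gas reference
    sample; emitter level is set (per wavelength) so the brightest point of
    the course sits just below full scale, following the dynamic-range
    protocol.  The MBLL inversion uses per-wavelength differential pathlength
    factors computed from the diffusion model at the phantom's designed
    baseline optical properties.  Returns the regression of the recovered
    saturation change on the reference saturation.
    """
    phantom = BloodPhantom() if phantom is None else phantom
    rig = default_rig() if rig is None else rig
    rng = np.random.default_rng(seed)
    if course is None:
        course = deoxygenation_course(duration_s, n_reference_samples,
                                      fs_hz=rig.fs_hz)
    so2_ref = course.reference_so2
    n_px = rig.layout.n_pixels(next(iter(rig.layout.spots)))

    mua = {wl: np.array([blood_mua(phantom, s, wl) for s in so2_ref])
           for wl in WAVELENGTHS}
    powers_per_step: Dict[Tuple[int, float], np.ndarray] = {}
    for wl in WAVELENGTHS:
        refl = kienle_reflectance(mua[wl], phantom.musp[wl], rig.rho_mm)
        p_full = power_for_electrons(operating_mgv * rig.sensor.conversion_gain,
                                     wl, rig.sensor, n_pixels=n_px)
        course_w = p_full * refl / refl.max()
        for ch in rig.cmap.channels:
            powers_per_step[(ch.channel_id, wl)] = course_w

    source_powers = _emitter_powers(rig, rng, 0.05)
    means = _channel_block_means(rig, powers_per_step, cycles_per_sample, rng,
                                 source_powers)

    pooled = {}
    for wl in WAVELENGTHS:
        mat = np.vstack([means[(ch.channel_id, wl)] for ch in rig.cmap.channels])
        pooled[wl] = mat.mean(axis=0)

    dpf = {wl: diffusion_dpf(float(mua[wl][0]), phantom.musp[wl], rig.rho_mm)
           for wl in WAVELENGTHS}
    table = pipeline.ExtinctionTable(
        eps={wl: phantom.eps(wl) for wl in WAVELENGTHS},
        dpf=dpf, pathlength_mm=rig.rho_mm)
    dod = {wl: pipeline.delta_od(pooled[wl], slice(0, 1)) for wl in WAVELENGTHS}
    hbo, hbr = pipeline.mbll_invert(dod, table)
    so2_0 = float(so2_ref[0])
    so2_est, dso2, _clipped = pipeline.estimate_so2(
        hbo, hbr, phantom.total_hemoglobin_mM, so2_0)
    slope, _, r2 = pipeline.linear_fit_r2(so2_ref, dso2)
    return DeoxygenationResult(reference_so2=so2_ref, recovered_dso2=dso2,
                               recovered_so2=so2_est, hbo_mM=hbo, hbr_mM=hbr,
                               r2=r2, slope=slope, dpf=dpf, course=course)


# ---------------------------------------------------------------------------
# verbal-fluency task
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VFTRunResult:
    times_s: np.ndarray
    truth_hbo_mM: np.ndarray
    truth_hbr_mM: np.ndarray
    recovered_hbo_mM: np.ndarray  # (n_channels, n_samples)
    recovered_hbr_mM: np.ndarray
    masks: Dict[int, pipeline.ArtifactMask]
    rejected_channels: Set[int]
    table: pipeline.ExtinctionTable
    fs_hz: float

    def mean_recovered(self) -> Tuple[np.ndarray, np.ndarray]:
        keep = [i for i in range(self.recovered_hbo_mM.shape[0])
                if (i + 1) not in self.rejected_channels]
        return (self.recovered_hbo_mM[keep].mean(axis=0),
                self.recovered_hbr_mM[keep].mean(axis=0))


def run_vft_experiment(design: Optional[VFTDesign] = None,
                       rig: Optional[Rig] = None, seed: int = 0,
                       operating_mgv: float = 335.0,
                       n_channels: Optional[int] = None,
                       through_sensor: bool = True,
                       band_hz: Tuple[float, float] = (0.01, 0.2),
                       table: Optional[pipeline.ExtinctionTable] = None
                       ) -> VFTRunResult:
    """Block-design task run through the preprocessing pipeline.

    Ground-truth hemodynamics are forward-projected to dual-wavelength
    intensities, optionally rendered through the camera, then processed:
    motion-artifact masking, OD conversion against the pre-task rest,
    zero-phase band-pass on the OD series, MBLL inversion, channel
    rejection.  In-vivo processing keeps the conventional DPF = 6.
    """
    design = VFTDesign() if design is None else design
    rig = default_rig() if rig is None else rig
    n_channels = len(rig.cmap) if n_channels is None else n_channels
    fs = rig.fs_hz
    rng = np.random.default_rng(seed)
    vft = vft_hemodynamics(design, fs, rng, n_channels=n_channels,
                           wavelengths=WAVELENGTHS)
    if table is None:
        table = pipeline.ExtinctionTable(
            eps={wl: phantoms.extinction_mm_mM(wl) for wl in WAVELENGTHS},
            dpf=dict(vft.dpf), pathlength_mm=vft.pathlength_mm)

    n_px = rig.layout.n_pixels(next(iter(rig.layout.spots)))
    intens: Dict[float, np.ndarray] = {}
    if through_sensor:
        courses = {}
        for wl in WAVELENGTHS:
            p0 = power_for_electrons(operating_mgv * rig.sensor.conversion_gain,
                                     wl, rig.sensor, n_pixels=n_px)
            for c in range(n_channels):
                cid = rig.cmap.channels[c].channel_id
                courses[(cid, wl)] = p0 * vft.intensities[wl][c]
        extracted = _extract_course(rig, courses, rng)
        base = slice(0, int(design.pre_rest_s * fs))
        for wl in WAVELENGTHS:
            mat = np.vstack([
                extracted[(rig.cmap.channels[c].channel_id, wl)]
                for c in range(n_channels)])
            intens[wl] = mat / mat[:, base].mean(axis=1, keepdims=True)
    else:
        intens = {wl: vft.intensities[wl].copy() for wl in WAVELENGTHS}

    n = intens[WAVELENGTHS[0]].shape[1]
    baseline = slice(0, int(design.pre_rest_s * fs))
    masks: Dict[int, pipeline.ArtifactMask] = {}
    hbo_all = np.empty((n_channels, n))
    hbr_all = np.empty((n_channels, n))
    for c in range(n_channels):
        m = np.zeros(n, dtype=bool)
        for wl in WAVELENGTHS:
            am = pipeline.detect_motion_artifacts(intens[wl][c], fs)
            m |= am.mask
        masks[c + 1] = pipeline.ArtifactMask(mask=m, std_thresh=10.0,
                                             amp_thresh=5.0, t_mask_s=0.5)
        dod = {}
        for wl in WAVELENGTHS:
            od = pipeline.delta_od(intens[wl][c], baseline)
            od = pipeline.interpolate_masked(od, m)
            dod[wl] = pipeline.bandpass_filter(od, fs, *band_hz)
        hbo_all[c], hbr_all[c] = pipeline.mbll_invert(dod, table)
        hbo_all[c][m] = np.nan
        hbr_all[c][m] = np.nan
    rejected, _fractions = pipeline.apply_rejection_rules(masks)
    return VFTRunResult(times_s=vft.times_s, truth_hbo_mM=vft.hbo_true_mM,
                        truth_hbr_mM=vft.hbr_true_mM,
                        recovered_hbo_mM=hbo_all, recovered_hbr_mM=hbr_all,
                        masks=masks, rejected_channels=rejected, table=table,
                        fs_hz=fs)


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------

def run_drift_experiment(model: Optional[DriftModel] = None,
                         duration_s: float = 3600.0, fs_hz: float = 5.0,
                         seed: int = 0) -> qc.DriftMetrics:
    """One-hour silicone-phantom stability run reduced to the drift triple."""
    model = DriftModel() if model is None else model
    stream = drift_series(model, duration_s, fs_hz, seed)
    return qc.drift_metrics(stream, fs_hz)
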