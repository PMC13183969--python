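"""Digital twin of the sCMOS sensor and the dual-wavelength light sources.

Photon-transfer noise model
---------------------------
Each pixel converts an expected photoelectron count ``mu`` into a digital
number as

    ADU = clip( round( (Poisson(mu) + Normal(0, Q)) / CG ) + bias, 0, 2^bits - 1 )

with read noise ``Q`` (electrons rms), conversion gain ``CG`` (electrons per
ADU) and an optional camera pedestal ``bias_adu`` (default 0).  Shot noise,
quantisation and the pedestal can each be disabled to obtain the noiseless
linear sensor used for round-trip identities.

The expected photoelectron count for optical power ``P`` (W) collected over
``N`` pixels during exposure ``t`` is ``P * t * eta * lambda / (h c) / N``.

Geometry
--------
Each detector fibre produces one circular speckle spot per wavelength on the
sensor; the two wavelengths are spectrally split onto the two halves of the
chip.  Spots are rendered with uniform mean flux (optional multiplicative
speckle contrast, default off) because downstream analysis only ever uses the
spot-mean gray value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .optode import ChannelMap, OptodeGrid, TDMSchedule

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "SensorSpec",
    "SourceSpec",
    "SpotLayout",
    "Frame",
    "expected_electrons",
    "power_for_electrons",
    "sample_adu",
    "render_frame",
    "simulate_stream",
    "source_irradiance",
    "mpe_skin",
    "default_layout",
]

# CODATA 2018 exact values
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 299792458.0  # m/s

WL_695 = 695.0
WL_830 = 830.0


@dataclass(frozen=True)
class SensorSpec:
    """Physical constants of the camera.

    Defaults follow the datasheet of a 4.2-megapixel 12-bit sCMOS sensor:
    read noise 3.57 e- rms, conversion gain 2.33 e-/ADU, quantum efficiency
    84.06% at 695 nm and 53.33% at 830 nm, 25 ms exposure.
    """

    width: int = 2048
    height: int = 2048
    bit_depth: int = 12
    read_noise_e: float = 3.57
    conversion_gain: float = 2.33  # electrons per ADU
    qe: Mapping[float, float] = field(
        default_factory=lambda: {WL_695: 0.8406, WL_830: 0.5333})
    exposure_s: float = 0.025
    bias_adu: float = 0.0  # camera pedestal, subtracted again at extraction
    shot_noise: bool = True
    quantize: bool = True
    speckle_contrast: float = 0.0  # multiplicative intra-spot texture, off by default

    def __post_init__(self) -> None:
        if self.conversion_gain <= 0:
            raise ValueError("conversion gain must be positive")
        for wl, eta in self.qe.items():
            if not (0 < eta <= 1):
                raise ValueError(f"quantum efficiency out of (0, 1] at {wl} nm: {eta}")

    @property
    def ceiling(self) -> int:
        return 2 ** self.bit_depth - 1

    def eta(self, wavelength_nm: float) -> float:
        try:
            return self.qe[wavelength_nm]
        except KeyError:
            raise KeyError(f"no quantum-efficiency entry for {wavelength_nm} nm") from None


@dataclass(frozen=True)
class SourceSpec:
    """Dual-wavelength emitter: both wavelengths share one transmission fibre."""

    wavelengths_nm: Tuple[float, float] = (WL_695, WL_830)
    power_mw: float = 4.0  # per wavelength, at the fibre tip
    fiber_tip_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.power_mw < 0:
            raise ValueError("power must be non-negative")
        if self.fiber_tip_diameter_mm <= 0:
            raise ValueError("fibre tip diameter must be positive")


@dataclass(frozen=True)
class Frame:
    """One exposure: 2-D ADU array plus its TDM slot bookkeeping."""

    data: np.ndarray
    timestamp_s: float
    slot: int  # slot index within the stream (cycle * n_groups + group)
    group: int  # active TDM group

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("frame data must be 2-D")


class SpotLayout:
    """Per (detector, wavelength) circular spot positions on the sensor.

    The 695 nm spots occupy the left half of the chip and the 830 nm spots the
    right half.  Spots must be disjoint and fully inside the sensor.
    """

    def __init__(self, spots: Mapping[Tuple[int, float], Tuple[float, float]],
                 radius_px: int, sensor: SensorSpec):
        if radius_px <= 0:
            raise ValueError("spot radius must be positive")
        self.spots = dict(spots)
        self.radius_px = int(radius_px)
        self.sensor = sensor
        self._masks: Dict[Tuple[int, float], Tuple[np.ndarray, np.ndarray]] = {}
        self._validate()

    def _validate(self) -> None:
        r = self.radius_px
        keys = list(self.spots)
        for key, (cx, cy) in self.spots.items():
            if not (r <= cx <= self.sensor.width - 1 - r and
                    r <= cy <= self.sensor.height - 1 - r):
                raise ValueError(f"spot {key} at ({cx}, {cy}) exceeds sensor bounds")
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                (ax, ay), (bx, by) = self.spots[a], self.spots[b]
                if math.hypot(ax - bx, ay - by) < 2 * r:
                    raise ValueError(f"spots {a} and {b} overlap")

    def pixel_indices(self, key: Tuple[int, float]) -> Tuple[np.ndarray, np.ndarray]:
        """(row, col) index arrays of pixels whose centres lie within the spot."""
        if key not in self._masks:
            cx, cy = self.spots[key]
            r = self.radius_px
            x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1
            y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            gx, gy = np.meshgrid(xs, ys)
            inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r ** 2
            self._masks[key] = (gy[inside], gx[inside])
        return self._masks[key]

    def n_pixels(self, key: Tuple[int, float]) -> int:
        return int(self.pixel_indices(key)[0].size)


def default_layout(grid: OptodeGrid, sensor: SensorSpec,
                   radius_px: int = 102,
                   wavelengths: Sequence[float] = (WL_695, WL_830)) -> SpotLayout:
    """Pack one spot per (detector, wavelength), one wavelength per sensor half."""
    n_det = grid.n_detectors
    half_w = sensor.width // 2
    pitch = 2 * radius_px + 6
    per_row = max(1, (half_w - 2 * radius_px) // pitch + 1)
    spots: Dict[Tuple[int, float], Tuple[float, float]] = {}
    for wi, wl in enumerate(wavelengths):
        x_off = wi * half_w
        for did in range(1, n_det + 1):
            i = did - 1
            row, col = divmod(i, per_row)
            cx = x_off + radius_px + 2 + col * pitch
            cy = radius_px + 2 + row * pitch
            spots[(did, wl)] = (float(cx), float(cy))
    return SpotLayout(spots, radius_px, sensor)


def expected_electrons(optical_power_w: float, wavelength_nm: float,
                       spec: SensorSpec, n_pixels: int = 1) -> float:
    """Mean photoelectrons per pixel per exposure: ``P t eta lambda / (h c) / N``."""
    if optical_power_w < 0:
        raise ValueError("optical power must be non-negative")
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    eta = spec.eta(wavelength_nm)
    lam_m = wavelength_nm * 1e-9
    return optical_power_w * spec.exposure_s * eta * lam_m / (PLANCK_H * SPEED_OF_LIGHT) / n_pixels


def power_for_electrons(mean_electrons: float, wavelength_nm: float,
                        spec: SensorSpec, n_pixels: int = 1) -> float:
    """Inverse of :func:`expected_electrons`: total power giving ``mean_electrons``/pixel."""
    eta = spec.eta(wavelength_nm)
    lam_m = wavelength_nm * 1e-9
    return mean_electrons * n_pixels * PLANCK_H * SPEED_OF_LIGHT / (spec.exposure_s * eta * lam_m)


def sample_adu(mean_electrons, spec: SensorSpec, rng: np.random.Generator,
               size=None) -> np.ndarray:
    """Draw ADU values for pixels with the given expected electron count.

    ``mean_electrons`` may be a scalar (with ``size``) or an array.  Output is
    uint16 when the sensor quantises, float64 otherwise.
    """
    mean = np.asarray(mean_electrons, dtype=float)
    if np.any(mean < 0):
        raise ValueError("mean electron count must be non-negative")
    if size is not None:
        mean = np.broadcast_to(mean, size)
    if spec.shot_noise and np.any(mean):
        electrons = rng.poisson(mean).astype(float)
    else:
        electrons = mean.astype(float, copy=True)
    if spec.read_noise_e > 0:
        electrons = electrons + rng.normal(0.0, spec.read_noise_e, size=electrons.shape)
    adu = electrons / spec.conversion_gain
    if spec.quantize:
        adu = np.rint(adu) + spec.bias_adu
        return np.clip(adu, 0, spec.ceiling).astype(np.uint16)
    adu = adu + spec.bias_adu
    return np.clip(adu, 0, spec.ceiling)


def render_frame(layout: SpotLayout, spot_powers_w: Mapping[Tuple[int, float], float],
                 spec: SensorSpec, rng: np.random.Generator,
                 slot: int = 0, group: int = 0, timestamp_s: float = 0.0) -> Frame:
    """Render one exposure: spot pixels from their flux, background read-noise only."""
    for key in spot_powers_w:
        if key not in layout.spots:
            raise KeyError(f"power given for unknown spot {key}")
    dtype = np.uint16 if spec.quantize else np.float64
    # background: zero-flux pixels
    frame = sample_adu(np.zeros((spec.height, spec.width)), spec, rng).astype(dtype)
    for key, power in spot_powers_w.items():
        rows, cols = layout.pixel_indices(key)
        n_px = rows.size
        mean = expected_electrons(power, key[1], spec, n_pixels=n_px)
        means = np.full(n_px, mean)
        if spec.speckle_contrast > 0:
            sigma = math.sqrt(math.log(1 + spec.speckle_contrast ** 2))
            means = means * rng.lognormal(-sigma ** 2 / 2, sigma, n_px)
        frame[rows, cols] = sample_adu(means, spec, rng)
    return Frame(data=frame, timestamp_s=timestamp_s, slot=slot, group=group)


def simulate_stream(schedule: TDMSchedule, cmap: ChannelMap,
                    channel_powers_w: Mapping[Tuple[int, float], np.ndarray],
                    spec: SensorSpec, layout: SpotLayout, seed) -> List[Frame]:
    """Render the ordered frame stream for per-channel power time-courses.

    ``channel_powers_w`` maps ``(channel_id, wavelength)`` to an array sampled
    at the schedule's cycle rate (one value per cycle).  During the slot of
    group ``g`` in cycle ``k``, detector ``d``'s spot at wavelength ``wl``
    receives the power of the channel whose source is active and adjacent to
    ``d``.  Returns one frame per on-slot (``n_cycles * n_groups`` frames).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lengths = {len(np.atleast_1d(v)) for v in channel_powers_w.values()}
    if len(lengths) != 1:
        raise ValueError("all channel power courses must have equal length")
    n_cycles = lengths.pop()
    chan = {ch.channel_id: ch for ch in cmap.channels}
    group_of = schedule.group_of_source
    # precompute which (channel, wl) feeds which spot in which group
    feeds: Dict[int, List[Tuple[Tuple[int, float], Tuple[int, float]]]] = {
        g: [] for g in range(schedule.n_groups)}
    for (cid, wl), _ in channel_powers_w.items():
        ch = chan[cid]
        g = group_of[ch.source_id]
        feeds[g].append(((cid, wl), (ch.detector_id, wl)))
    frames: List[Frame] = []
    cycle_s = schedule.cycle_ms / 1000.0
    slot_s = (schedule.on_ms + schedule.off_ms) / 1000.0
    for k in range(n_cycles):
        for g in range(schedule.n_groups):
            powers: Dict[Tuple[int, float], float] = {}
            for (cid, wl), spot in feeds[g]:
                powers[spot] = powers.get(spot, 0.0) + float(np.atleast_1d(
                    channel_powers_w[(cid, wl)])[k])
            frames.append(render_frame(
                layout, powers, spec, rng,
                slot=k * schedule.n_groups + g, group=g,
                timestamp_s=k * cycle_s + g * slot_s))
    return frames


def source_irradiance(spec: SourceSpec) -> Dict[float, float]:
    """Fibre-tip irradiance in mW/cm^2 per wavelength: ``P / (pi (d/2)^2)``."""
    if spec.fiber_tip_diameter_mm <= 0:
        raise ValueError("fibre tip diameter must be positive")
    area_cm2 = math.pi * (spec.fiber_tip_diameter_mm / 2 / 10) ** 2
    return {wl: spec.power_mw / area_cm2 for wl in spec.wavelengths_nm}


def mpe_skin(wavelength_nm: float) -> float:
    """ANSI Z136.1 CW skin maximum permissible exposure, mW/cm^2.

    ``200 * C_A`` with ``C_A = 1`` for 400-700 nm and
    ``C_A = 10^(2 (lambda_um - 0.700))`` for 700-1050 nm; constant above
    1050 nm up to 1400 nm.
    """
    if not (400 <= wavelength_nm <= 1400):
        raise ValueError(f"wavelength {wavelength_nm} nm outside supported 400-1400 nm band")
    lam_um = wavelength_nm / 1000.0
    if lam_um <= 0.700:
        ca = 1.0
    elif lam_um <= 1.050:
        ca = 10 ** (2 * (lam_um - 0.700))
    else:
        ca = 5.0
    return 200.0 * ca
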