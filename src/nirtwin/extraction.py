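"""Frame-stream reduction: ROI averaging, TDM demultiplexing, normalisation.

The camera stream is turned into per-channel, per-wavelength mean-gray-value
(MGV) time series: each detector has one circular region of interest per
wavelength, the MGV is the arithmetic mean ADU over pixels whose centres lie
within the ROI radius, and the TDM slot structure assigns each MGV reading to
the channel whose source was active in that slot.  Missing slots are marked
NaN, never interpolated.  The camera pedestal configured on the sensor is
subtracted so MGV values are signal-referred.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .optode import ChannelMap, TDMSchedule
from .sensor import Frame, SensorSpec, SpotLayout

__all__ = [
    "ROISpec",
    "ChannelTimeSeries",
    "mean_gray_value",
    "rois_from_layout",
    "demultiplex",
    "normalize_by_source",
    "flag_saturation",
    "SaturationReport",
]


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest on the sensor for one detector/wavelength."""

    center_xy: Tuple[float, float]  # pixel coordinates, x right, y down, 0-based
    radius_px: int
    wavelength_nm: float
    detector_id: int

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("ROI radius must be positive")

    def pixel_indices(self, width: int, height: int) -> Tuple[np.ndarray, np.ndarray]:
        cx, cy = self.center_xy
        r = self.radius_px
        if not (r <= cx <= width - 1 - r and r <= cy <= height - 1 - r):
            raise ValueError(f"ROI at ({cx}, {cy}) radius {r} exceeds frame bounds")
        x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1
        y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1
        gx, gy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r ** 2
        return gy[inside], gx[inside]


@dataclass
class ChannelTimeSeries:
    """Uniformly sampled per-channel series at one wavelength.

    ``values`` are pedestal-subtracted MGVs (ADU) or, after
    :func:`normalize_by_source`, normalised intensities.  ``saturated`` marks
    cycles whose raw MGV reached the ADU ceiling.
    """

    channel_id: int
    wavelength_nm: float
    values: np.ndarray
    sampling_rate_hz: float
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_power_reference_mw: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.saturated is None:
            self.saturated = np.zeros(self.values.shape, dtype=bool)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        if self.saturated.shape != self.values.shape:
            raise ValueError("saturation flags must match series length")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate_hz


def mean_gray_value(frame: Frame, roi: ROISpec, *,
                    bias_adu: float = 0.0) -> float:
    """Arithmetic mean ADU over the ROI disc, minus the camera pedestal."""
    h, w = frame.data.shape
    rows, cols = roi.pixel_indices(w, h)
    return float(frame.data[rows, cols].mean()) - bias_adu


def rois_from_layout(layout: SpotLayout) -> Dict[Tuple[int, float], ROISpec]:
    """One ROI per (detector, wavelength), centred on the layout's spots."""
    return {
        (did, wl): ROISpec(center_xy=center, radius_px=layout.radius_px,
                           wavelength_nm=wl, detector_id=did)
        for (did, wl), center in layout.spots.items()
    }


def demultiplex(frames: Sequence[Frame], schedule: TDMSchedule, cmap: ChannelMap,
                rois: Mapping[Tuple[int, float], ROISpec],
                sensor: Optional[SensorSpec] = None) -> Dict[Tuple[int, float], ChannelTimeSeries]:
    """Per-channel dual-wavelength MGV series from an ordered frame stream.

    The value of channel (s, d) at cycle k is the MGV of detector d's ROI in
    the frame of cycle k whose active group is s's group.  Slots missing from
    the stream yield NaN values flagged unsaturated.  Series length equals the
    number of complete cycles, ``floor(n_frames / n_groups)`` when no slots
    are missing.
    """
    bias = sensor.bias_adu if sensor is not None else 0.0
    ceiling = sensor.ceiling if sensor is not None else None
    by_slot = {f.slot: f for f in frames}
    if len(by_slot) != len(frames):
        raise ValueError("duplicate slot indices in frame stream")
    n_groups = schedule.n_groups
    max_slot = max(by_slot) if by_slot else -1
    n_cycles = (max_slot + n_groups) // n_groups if by_slot else 0
    missing = [s for s in range(n_cycles * n_groups) if s not in by_slot]
    if missing:
        warnings.warn(f"{len(missing)} missing slots; affected samples set to NaN",
                      stacklevel=2)

    # cache MGV per (slot, detector, wl) lazily
    mgv_cache: Dict[Tuple[int, int, float], float] = {}

    def mgv(slot: int, did: int, wl: float) -> Tuple[float, bool]:
        key = (slot, did, wl)
        if key not in mgv_cache:
            frame = by_slot[slot]
            roi = rois[(did, wl)]
            raw = mean_gray_value(frame, roi, bias_adu=0.0)
            mgv_cache[key] = raw
        raw = mgv_cache[key]
        sat = ceiling is not None and raw >= ceiling
        return raw - bias, sat

    wavelengths = sorted({wl for (_d, wl) in rois})
    out: Dict[Tuple[int, float], ChannelTimeSeries] = {}
    for ch in cmap.channels:
        g = schedule.group_of_source[ch.source_id]
        for wl in wavelengths:
            values = np.full(n_cycles, np.nan)
            sat = np.zeros(n_cycles, dtype=bool)
            for k in range(n_cycles):
                slot = k * n_groups + g
                if slot in by_slot:
                    frame = by_slot[slot]
                    if frame.group != g:
                        raise ValueError(
                            f"frame at slot {slot} tagged group {frame.group}, "
                            f"schedule expects {g}")
                    values[k], sat[k] = mgv(slot, ch.detector_id, wl)
            out[(ch.channel_id, wl)] = ChannelTimeSeries(
                channel_id=ch.channel_id, wavelength_nm=wl, values=values,
                sampling_rate_hz=schedule.sampling_rate_hz, saturated=sat)
    return out


def normalize_by_source(series: Mapping[Tuple[int, float], ChannelTimeSeries],
                        cmap: ChannelMap,
                        source_powers_mw: Mapping[int, float]
                        ) -> Dict[Tuple[int, float], ChannelTimeSeries]:
    """Divide each channel by its emitter's measured power (mW).

    Removes emitter-to-emitter intensity variation; invariant to a global
    rescaling of all powers up to a constant factor.
    """
    chan = {ch.channel_id: ch for ch in cmap.channels}
    out: Dict[Tuple[int, float], ChannelTimeSeries] = {}
    for key, ts in series.items():
        sid = chan[ts.channel_id].source_id
        power = source_powers_mw.get(sid)
        if power is None or power <= 0:
            raise ValueError(f"missing or non-positive power for source {sid}")
        out[key] = replace(ts, values=ts.values / power,
                           source_power_reference_mw=power)
    return out


@dataclass(frozen=True)
class SaturationReport:
    flags: np.ndarray
    fraction: float
    warn: bool  # True when more than 0.1% of samples sit at the ceiling


def flag_saturation(ts: ChannelTimeSeries, ceiling: int = 4095,
                    bias_adu: float = 0.0) -> SaturationReport:
    """Flag samples whose MGV reached the ADU ceiling (pedestal-aware)."""
    flags = ts.values >= (ceiling - bias_adu)
    frac = float(flags.mean()) if flags.size else 0.0
    return SaturationReport(flags=flags, fraction=frac, warn=frac > 0.001)
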