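"""Interchange formats: TIFF/HDF5 frame containers, CSV series, SNIRF, JSON.

Frame stacks travel as multi-page 16-bit TIFF with a JSON sidecar carrying
the schedule, layout and seed, or as a single HDF5 container with the same
keys.  Channel series use a flat CSV schema
``time_s, channel_id, wavelength_nm, mgv, saturated``.  Continuous-wave
amplitude blocks are written as minimal SNIRF v1.0 (an HDF5 profile); the
reader validates the structural essentials on load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
import tifffile

from .extraction import ChannelTimeSeries
from .sensor import Frame

__all__ = [
    "write_frames_tiff",
    "read_frames_tiff",
    "write_frames_hdf5",
    "read_frames_hdf5",
    "write_series_csv",
    "read_series_csv",
    "write_snirf",
    "read_snirf",
    "write_json_report",
    "FormatError",
]


class FormatError(ValueError):
    """Malformed or truncated interchange file."""


def _sidecar(frames: Sequence[Frame], meta: Optional[Mapping] = None) -> Dict:
    return {
        "n_frames": len(frames),
        "timestamps_s": [f.timestamp_s for f in frames],
        "slots": [f.slot for f in frames],
        "groups": [f.group for f in frames],
        "meta": dict(meta) if meta else {},
    }


def write_frames_tiff(path, frames: Sequence[Frame],
                      meta: Optional[Mapping] = None) -> None:
    """Multi-page 16-bit TIFF plus a ``<path>.json`` sidecar."""
    path = Path(path)
    stack = np.stack([np.asarray(f.data, dtype=np.uint16) for f in frames])
    tifffile.imwrite(path, stack)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(_sidecar(frames, meta), indent=1))


def read_frames_tiff(path) -> Tuple[List[Frame], Dict]:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    try:
        stack = tifffile.imread(path)
        side = json.loads(sidecar_path.read_text())
    except Exception as exc:  # noqa: BLE001 - surfacing parser errors uniformly
        raise FormatError(f"cannot read frame stack {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    if side.get("n_frames") != stack.shape[0]:
        raise FormatError(
            f"sidecar lists {side.get('n_frames')} frames, file holds {stack.shape[0]}")
    frames = [Frame(data=stack[i], timestamp_s=side["timestamps_s"][i],
                    slot=side["slots"][i], group=side["groups"][i])
              for i in range(stack.shape[0])]
    return frames, side.get("meta", {})


def write_frames_hdf5(path, frames: Sequence[Frame],
                      meta: Optional[Mapping] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=np.stack(
            [np.asarray(fr.data, dtype=np.uint16) for fr in frames]))
        f.create_dataset("timestamps_s", data=[fr.timestamp_s for fr in frames])
        f.create_dataset("slots", data=[fr.slot for fr in frames])
        f.create_dataset("groups", data=[fr.group for fr in frames])
        f.attrs["meta"] = json.dumps(dict(meta) if meta else {})


def read_frames_hdf5(path) -> Tuple[List[Frame], Dict]:
    try:
        with h5py.File(path, "r") as f:
            for key in ("frames", "timestamps_s", "slots", "groups"):
                if key not in f:
                    raise FormatError(f"missing dataset '{key}' in {path}")
            stack = f["frames"][...]
            ts = f["timestamps_s"][...]
            slots = f["slots"][...]
            groups = f["groups"][...]
            meta = json.loads(f.attrs.get("meta", "{}"))
    except OSError as exc:
        raise FormatError(f"cannot open HDF5 container {path}: {exc}") from exc
    frames = [Frame(data=stack[i], timestamp_s=float(ts[i]),
                    slot=int(slots[i]), group=int(groups[i]))
              for i in range(stack.shape[0])]
    return frames, meta


# ---------------------------------------------------------------------------
# channel series CSV
# ---------------------------------------------------------------------------

def write_series_csv(path, series: Mapping[Tuple[int, float], ChannelTimeSeries]
                     ) -> None:
    """Flat long-format CSV: time_s, channel_id, wavelength_nm, mgv, saturated."""
    rows = []
    for (cid, wl), ts in sorted(series.items()):
        for t, v, s in zip(ts.times_s, ts.values, ts.saturated):
            rows.append((t, cid, wl, v, int(s)))
    df = pd.DataFrame(rows, columns=["time_s", "channel_id", "wavelength_nm",
                                     "mgv", "saturated"])
    df.to_csv(path, index=False)


def read_series_csv(path) -> Dict[Tuple[int, float], ChannelTimeSeries]:
    df = pd.read_csv(path)
    required = {"time_s", "channel_id", "wavelength_nm", "mgv", "saturated"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"series CSV missing columns {sorted(missing)}")
    out: Dict[Tuple[int, float], ChannelTimeSeries] = {}
    for (cid, wl), g in df.groupby(["channel_id", "wavelength_nm"]):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
        out[(int(cid), float(wl))] = ChannelTimeSeries(
            channel_id=int(cid), wavelength_nm=float(wl),
            values=g["mgv"].to_numpy(), sampling_rate_hz=float(fs),
            saturated=g["saturated"].to_numpy().astype(bool))
    return out


# ---------------------------------------------------------------------------
# SNIRF (minimal v1.0 continuous-wave profile)
# ---------------------------------------------------------------------------

def _h5str(value: str):
    return np.bytes_(value.encode())


def write_snirf(path, series: Mapping[Tuple[int, float], ChannelTimeSeries],
                source_of_channel: Mapping[int, int],
                detector_of_channel: Mapping[int, int],
                source_pos_mm: Optional[Mapping[int, Tuple[float, float, float]]] = None,
                detector_pos_mm: Optional[Mapping[int, Tuple[float, float, float]]] = None
                ) -> None:
    """Write continuous-wave amplitude blocks as a minimal SNIRF file.

    One ``/nirs/data1`` block with a measurementList entry per
    (channel, wavelength) column, dataType 1 (CW amplitude).
    """
    keys = sorted(series)
    wavelengths = sorted({wl for _c, wl in keys})
    ts0 = series[keys[0]]
    n = ts0.values.size
    data = np.column_stack([series[k].values for k in keys])
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=_h5str("1.0"))
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, float))
        sids = sorted(set(source_of_channel.values()))
        dids = sorted(set(detector_of_channel.values()))
        spos = np.array([source_pos_mm[s] if source_pos_mm else (0.0, 0.0, 0.0)
                         for s in sids])
        dpos = np.array([detector_pos_mm[d] if detector_pos_mm else (0.0, 0.0, 0.0)
                         for d in dids])
        probe.create_dataset("sourcePos3D", data=spos.reshape(len(sids), 3))
        probe.create_dataset("detectorPos3D", data=dpos.reshape(len(dids), 3))
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=ts0.times_s)
        for i, (cid, wl) in enumerate(keys, start=1):
            ml = d1.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex",
                              data=sids.index(source_of_channel[cid]) + 1)
            ml.create_dataset("detectorIndex",
                              data=dids.index(detector_of_channel[cid]) + 1)
            ml.create_dataset("wavelengthIndex", data=wavelengths.index(wl) + 1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=cid)


def read_snirf(path) -> Dict[Tuple[int, float], ChannelTimeSeries]:
    """Read the continuous-wave amplitude block of a SNIRF file."""
    try:
        with h5py.File(path, "r") as f:
            if "formatVersion" not in f or "nirs" not in f:
                raise FormatError(f"{path} is not a SNIRF file")
            d1 = f["nirs"]["data1"]
            data = d1["dataTimeSeries"][...]
            time = d1["time"][...]
            wavelengths = f["nirs"]["probe"]["wavelengths"][...]
            out: Dict[Tuple[int, float], ChannelTimeSeries] = {}
            fs = 1.0 / float(np.median(np.diff(time))) if time.size > 1 else 1.0
            i = 1
            while f"measurementList{i}" in d1:
                ml = d1[f"measurementList{i}"]
                if int(ml["dataType"][()]) != 1:
                    raise FormatError("only CW amplitude blocks are supported")
                wl = float(wavelengths[int(ml["wavelengthIndex"][()]) - 1])
                cid = int(ml["dataTypeIndex"][()])
                out[(cid, wl)] = ChannelTimeSeries(
                    channel_id=cid, wavelength_nm=wl, values=data[:, i - 1],
                    sampling_rate_hz=fs)
                i += 1
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read SNIRF file {path}: {exc}") from exc
    return out


def write_json_report(path, report: Mapping) -> None:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, set):
            return sorted(obj)
        raise TypeError(f"unserialisable {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=1, default=default))
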