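"""Run configuration: TOML-backed, schema-validated, written back with results.

Unknown keys are rejected so typos fail loudly.  Every CLI run writes its
fully resolved configuration next to the outputs, and a single master seed
fans out to named sub-streams (sensor, phantom, artifacts) so stages remain
reproducible even when run separately.
"""

from __future__ import annotations

import json
import logging
import tomllib
import zlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

logger = logging.getLogger("nirtwin")

__all__ = ["RunConfig", "GeometryConfig", "SensorConfig", "ExperimentConfig",
           "PipelineConfig", "load_config", "dump_resolved", "subseed", "rng_for"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    rows: int = 3
    cols: int = 11
    pitch_mm: float = 30.0
    n_groups: int = 4
    on_ms: float = 25.0
    off_ms: float = 25.0


class SensorConfig(_Strict):
    width: int = 2048
    height: int = 2048
    bit_depth: int = 12
    read_noise_e: float = 3.57
    conversion_gain: float = 2.33
    qe_695: float = 0.8406
    qe_830: float = 0.5333
    exposure_s: float = 0.025
    bias_adu: float = 100.0
    spot_radius_px: int = 102
    shot_noise: bool = True
    quantize: bool = True


class ExperimentConfig(_Strict):
    kind: Literal["titration", "deoxygenation", "vft", "drift",
                  "snr_protocol", "dor_protocol"] = "vft"
    # titration
    preset: Literal["baseline", "low", "high"] = "baseline"
    n_steps: int = 9
    cycles_per_step: int = 3
    operating_mgv: float = 335.0
    # deoxygenation
    duration_s: float = 600.0
    n_reference_samples: int = 12
    cycles_per_sample: int = 6
    deoxy_operating_mgv: float = 3600.0
    # drift
    drift_rate_pct_per_h: float = 0.4
    drift_duration_s: float = 3600.0
    drift_fs_hz: float = 5.0
    # snr protocol
    state_a_mgv: float = 335.0
    snr_repeats: int = 4
    # dor protocol
    mgv_max: float = 4095.0
    mgv_min_695: float = 1.87
    mgv_min_830: float = 1.92


class PipelineConfig(_Strict):
    std_thresh: float = 10.0
    amp_thresh: float = 5.0
    t_mask_s: float = 0.5
    low_hz: float = 0.01
    high_hz: float = 0.2
    dpf: float = 6.0
    pathlength_mm: float = 30.0


class RunConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    geometry: GeometryConfig = GeometryConfig()
    sensor: SensorConfig = SensorConfig()
    experiment: ExperimentConfig = ExperimentConfig()
    pipeline: PipelineConfig = PipelineConfig()


def load_config(path: Optional[str]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    return RunConfig.model_validate(raw)


def dump_resolved(cfg: RunConfig, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    target = out_dir / "resolved_config.json"
    target.write_text(json.dumps(cfg.model_dump(), indent=1, sort_keys=True))
    return target


def subseed(master_seed: int, label: str) -> int:
    """Deterministic per-component seed derived from the master seed (< 2^31)."""
    return (master_seed * 1000003 + zlib.crc32(label.encode())) % (2 ** 31 - 1)


def rng_for(master_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(subseed(master_seed, label))
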