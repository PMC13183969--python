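"""Preprocessing and chromophore mathematics for dual-wavelength CW series.

The processing order mirrors standard fNIRS practice: prune channels that do
not respond to an absorber titration, mask motion artifacts with windowed
change detection (thresholds on windowed excursion relative to the robust
derivative scale and on absolute amplitude, the flagged instants dilated by a
guard window), reject channels with too much contamination, band-pass filter
(zero-phase Butterworth, 0.01-0.2 Hz), convert to optical density changes
against a baseline window, invert the modified Beer-Lambert law per sample,
and derive saturation changes and the regression/correlation statistics.

Masked samples are bridged by linear interpolation before filtering so their
values can never leak into the output, and are excluded from all statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Set, Tuple

import numpy as np
from scipy import signal, stats

__all__ = [
    "ArtifactMask",
    "ExtinctionTable",
    "HemoSeries",
    "CorrelationResult",
    "prune_nonresponsive",
    "detect_motion_artifacts",
    "apply_rejection_rules",
    "exclude_channel_pairs",
    "bandpass_filter",
    "delta_od",
    "mbll_forward",
    "mbll_invert",
    "estimate_so2",
    "sqrt_transform",
    "linear_fit_r2",
    "correlate_channels",
]


# ---------------------------------------------------------------------------
# channel pruning (titration responsiveness)
# ---------------------------------------------------------------------------

def prune_nonresponsive(titration_series: Mapping[int, Mapping[float, np.ndarray]],
                        mua_series: np.ndarray) -> Set[int]:
    """Channels retained after the titration-responsiveness check.

    A channel is pruned only when its fitted signal-vs-mu_a slope is
    non-negative at *both* wavelengths (no reduction at either wavelength
    while the absorber increases).
    """
    mua = np.asarray(mua_series, dtype=float)
    if mua.size < 3:
        raise ValueError("need at least 3 titration points")
    retained: Set[int] = set()
    for cid, per_wl in titration_series.items():
        flat_everywhere = True
        for wl, values in per_wl.items():
            slope, _ = np.polyfit(mua, np.asarray(values, dtype=float), 1)
            if slope < 0:
                flat_everywhere = False
                break
        if not flat_everywhere:
            retained.add(cid)
    return retained


# ---------------------------------------------------------------------------
# motion artifacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactMask:
    """Per-sample contamination mask with the parameters that produced it."""

    mask: np.ndarray
    std_thresh: float
    amp_thresh: float
    t_mask_s: float

    @property
    def fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


def detect_motion_artifacts(values: np.ndarray, fs_hz: float,
                            std_thresh: float = 10.0,
                            amp_thresh: float = 5.0,
                            t_mask_s: float = 0.5,
                            window_s: float = 0.5) -> ArtifactMask:
    """Windowed motion-artifact detection.

    A window of ``window_s`` slides sample-by-sample; the samples of any
    window whose peak-to-peak excursion exceeds ``std_thresh`` times the
    robust (MAD-based) standard deviation of the sample-to-sample differences,
    or exceeds ``amp_thresh`` in the signal's own units, are flagged.  Flags
    are then dilated by ``t_mask_s`` on each side.  Window membership is
    inclusive of both endpoints of the window span.
    """
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    x = np.asarray(values, dtype=float)
    w = max(2, int(round(window_s * fs_hz)) + 1)
    if x.size < w:
        raise ValueError(f"series shorter than the {window_s} s evaluation window")
    diffs = np.diff(x)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    sd_ref = 1.4826 * mad
    if sd_ref == 0:
        sd_ref = diffs.std() or np.inf  # flat signal: nothing can exceed it

    mask = np.zeros(x.size, dtype=bool)
    # rolling peak-to-peak via strided max/min
    view = np.lib.stride_tricks.sliding_window_view(x, w)
    ptp = view.max(axis=1) - view.min(axis=1)
    hits = (ptp > std_thresh * sd_ref) | (ptp > amp_thresh)
    for i in np.flatnonzero(hits):
        mask[i:i + w] = True
    if mask.any():
        guard = int(round(t_mask_s * fs_hz))
        idx = np.flatnonzero(mask)
        for i in idx:
            mask[max(0, i - guard):i + guard + 1] = True
    return ArtifactMask(mask=mask, std_thresh=std_thresh,
                        amp_thresh=amp_thresh, t_mask_s=t_mask_s)


def apply_rejection_rules(masks: Mapping[int, ArtifactMask],
                          contamination_threshold: float = 0.05
                          ) -> Tuple[Set[int], Dict[int, float]]:
    """Reject channels with more than 5% contaminated time points (strict >).

    Returns (rejected channel ids, per-channel contaminated fraction).
    Idempotent: re-running on the surviving channels is a no-op.
    """
    fractions = {cid: m.fraction for cid, m in masks.items()}
    rejected = {cid for cid, frac in fractions.items()
                if frac > contamination_threshold}
    return rejected, fractions


def exclude_channel_pairs(bad_by_participant: Mapping[str, Set[int]],
                          n_channels: int,
                          session_threshold: float = 0.30) -> Set[str]:
    """Sessions whose channel-pair data are excluded.

    A session is excluded when more than 30% of its channels are marked bad
    in at least one participant (strict >).
    """
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    return {pid for pid, bad in bad_by_participant.items()
            if len(bad) / n_channels > session_threshold}


# ---------------------------------------------------------------------------
# filtering and optical density
# ---------------------------------------------------------------------------

def bandpass_filter(values: np.ndarray, fs_hz: float,
                    low_hz: float = 0.01, high_hz: float = 0.2,
                    order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, order 3).

    Removes DC along with cardiac/respiratory oscillations above the upper
    cutoff.  Requires ``fs > 2 * high``.
    """
    if fs_hz <= 2 * high_hz:
        raise ValueError(f"cutoff {high_hz} Hz infeasible at fs = {fs_hz} Hz")
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low < high")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=fs_hz, output="sos")
    x = np.asarray(values, dtype=float)
    return signal.sosfiltfilt(sos, x)


def delta_od(values: np.ndarray, baseline: slice | np.ndarray) -> np.ndarray:
    """Optical-density change ``-log10(I / I0)`` against the baseline-window mean."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("intensities must be positive for an OD conversion")
    i0 = x[baseline].mean()
    if not np.isfinite(i0) or i0 <= 0:
        raise ValueError("baseline window empty or non-positive")
    return -np.log10(x / i0)


# ---------------------------------------------------------------------------
# modified Beer-Lambert law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients and pathlength scaling for the MBLL inversion.

    ``eps[wl] = (eps_HbO, eps_HbR)`` in mm^-1 mM^-1 (decadic), ``dpf[wl]``
    the differential pathlength factor, ``pathlength_mm`` the source-detector
    separation.  The 2x2 system must be well conditioned.
    """

    eps: Mapping[float, Tuple[float, float]]
    dpf: Mapping[float, float]
    pathlength_mm: float = 30.0
    max_condition: float = 1e6

    def __post_init__(self) -> None:
        if len(self.eps) != 2:
            raise ValueError("exactly two operating wavelengths required")
        cond = np.linalg.cond(self.matrix())
        if not np.isfinite(cond) or cond > self.max_condition:
            raise ValueError(f"extinction matrix ill-conditioned (cond = {cond:.3g})")

    @property
    def wavelengths(self) -> Tuple[float, float]:
        return tuple(sorted(self.eps))  # type: ignore[return-value]

    def matrix(self) -> np.ndarray:
        """Rows per wavelength: [eps_HbO, eps_HbR] * L * DPF(wl)."""
        rows = []
        for wl in sorted(self.eps):
            eo, er = self.eps[wl]
            scale = self.pathlength_mm * self.dpf[wl]
            rows.append([eo * scale, er * scale])
        return np.asarray(rows)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix()))


def mbll_forward(hbo_mM: np.ndarray, hbr_mM: np.ndarray,
                 table: ExtinctionTable) -> Dict[float, np.ndarray]:
    """Project concentration changes to per-wavelength optical-density changes."""
    m = table.matrix()
    out = {}
    for i, wl in enumerate(sorted(table.eps)):
        out[wl] = m[i, 0] * np.asarray(hbo_mM, float) + m[i, 1] * np.asarray(hbr_mM, float)
    return out


def mbll_invert(dod: Mapping[float, np.ndarray],
                table: ExtinctionTable) -> Tuple[np.ndarray, np.ndarray]:
    """Solve the per-sample 2x2 system for (dHbO, dHbR) in mM."""
    wls = sorted(table.eps)
    if sorted(dod) != wls:
        raise ValueError(f"dOD wavelengths {sorted(dod)} do not match table {wls}")
    m = table.matrix()
    inv = np.linalg.inv(m)
    stacked = np.vstack([np.asarray(dod[wl], dtype=float) for wl in wls])
    sol = inv @ stacked
    return sol[0], sol[1]


@dataclass(frozen=True)
class HemoSeries:
    """Concentration-change series for one channel, with derived saturation."""

    times_s: np.ndarray
    hbo_mM: np.ndarray
    hbr_mM: np.ndarray
    sampling_rate_hz: float
    dso2: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None  # True where contaminated


def estimate_so2(hbo_mM: np.ndarray, hbr_mM: np.ndarray,
                 baseline_thb_mM: float, baseline_so2: float
                 ) -> Tuple[np.ndarray, np.ndarray, int]:
    """Saturation estimate from concentration changes against a known baseline.

    ``SO2(t) = (HbO0 + dHbO) / (tHb0 + dHbO + dHbR)`` clipped to [0, 1];
    returns (SO2 estimate, dSO2 = SO2 - SO2_0, number of clipped samples).
    """
    if baseline_thb_mM <= 0:
        raise ValueError("baseline tHb must be positive")
    if not (0 <= baseline_so2 <= 1):
        raise ValueError("baseline SO2 must lie in [0, 1]")
    hbo0 = baseline_so2 * baseline_thb_mM
    num = hbo0 + np.asarray(hbo_mM, float)
    den = baseline_thb_mM + np.asarray(hbo_mM, float) + np.asarray(hbr_mM, float)
    if np.any(den <= 0):
        raise ValueError("non-positive total haemoglobin in SO2 estimate")
    so2 = num / den
    clipped = int(np.sum((so2 < 0) | (so2 > 1)))
    so2 = np.clip(so2, 0.0, 1.0)
    return so2, so2 - baseline_so2, clipped


def sqrt_transform(values: np.ndarray) -> np.ndarray:
    """Element-wise square root; stabilises the variance of Poisson noise (~1/4)."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("square-root transform requires non-negative values")
    return np.sqrt(x)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def linear_fit_r2(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Ordinary least squares: (slope, intercept, R^2 = 1 - SS_res/SS_tot)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.var(x) == 0:
        raise ValueError("var(x) = 0: regression undefined")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(res.slope), float(res.intercept), r2


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float
    normal_a: bool
    normal_b: bool


def correlate_channels(a: np.ndarray, b: np.ndarray,
                       alpha: float = 0.05) -> CorrelationResult:
    """Normality-gated correlation.

    Shapiro-Wilk on both series at level ``alpha``; Pearson when both pass,
    Spearman otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need equal-length inputs with n >= 5")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("constant input: correlation undefined")
    pa = stats.shapiro(a).pvalue
    pb = stats.shapiro(b).pvalue
    normal_a, normal_b = pa > alpha, pb > alpha
    if normal_a and normal_b:
        r = stats.pearsonr(a, b)
        return CorrelationResult("pearson", float(r.statistic), float(r.pvalue),
                                 normal_a, normal_b)
    r = stats.spearmanr(a, b)
    return CorrelationResult("spearman", float(r.statistic), float(r.pvalue),
                             normal_a, normal_b)


# ---------------------------------------------------------------------------
# masked processing helper
# ---------------------------------------------------------------------------

def interpolate_masked(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Bridge masked samples linearly so they cannot influence filtering."""
    x = np.asarray(values, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return x
    if mask.all():
        raise ValueError("all samples masked")
    idx = np.arange(x.size)
    x[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    return x
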