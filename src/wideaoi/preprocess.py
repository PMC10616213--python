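"""Gaze-stream cleaning: spike filtering, gap handling, uniform resampling.

The pipeline order is fixed and deterministic:

1. :func:`median_filter` — running median (window 3) for one-sample spikes;
2. :func:`classify_gaps` — samples with pupil confidence below 0.8 or off the
   display are marked as gaps (blinks, tracking loss, excursions);
3. :func:`interpolate_short_gaps` — gaps shorter than 75 ms are bridged by
   linear interpolation (too short for a real blink, typically flicker);
4. :func:`extend_gaps` — the ±100 ms around each remaining gap is also
   treated as gap, covering partial pupil occlusion at blink edges;
5. :func:`resample_uniform` — the two 120 Hz eye cameras sample in anti-phase
   and their merged stream is not perfectly regular, so the stream is
   resampled to a uniform 240 Hz grid with shape-preserving cubic Hermite
   (PCHIP) interpolation, computed per contiguous valid segment.

Resampling never bridges invalid spans: interpolation across gaps is the
exclusive job of step 3.

Gaze streams are DataFrames with columns ``t, x, y, confidence, on_screen,
valid`` (see :mod:`wideaoi.io_gaze`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "PreprocessParams",
    "GapStats",
    "median_filter",
    "classify_gaps",
    "interpolate_short_gaps",
    "extend_gaps",
    "resample_uniform",
    "gap_stats",
    "preprocess_pipeline",
]

_EPS_S = 1e-9  # float-safety slack, orders of magnitude below a sample period


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable preprocessing parameters (defaults = validated setup).

    median_window: samples, odd; confidence_threshold: strict lower bound for
    keeping a sample; max_interp_gap_ms: gaps strictly shorter are linearly
    interpolated; gap_pad_ms: dilation of remaining gaps (inclusive);
    target_rate_hz: uniform output rate.
    """

    median_window: int = 3
    confidence_threshold: float = 0.8
    max_interp_gap_ms: float = 75.0
    gap_pad_ms: float = 100.0
    target_rate_hz: float = 240.0

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.max_interp_gap_ms < 0 or self.gap_pad_ms < 0:
            raise ValueError("gap durations must be non-negative")
        if self.target_rate_hz <= 0:
            raise ValueError("target_rate_hz must be positive")


@dataclass(frozen=True)
class GapStats:
    """Percentages of missing samples after each preprocessing stage."""

    pct_low_confidence: float
    pct_off_screen: float
    pct_nan_before_interp: float
    pct_nan_after_interp: float
    pct_nan_after_pad: float


def _invalid_runs(valid: np.ndarray):
    """Maximal runs of False as (start, stop) index pairs, stop exclusive."""
    inv = ~valid
    if not inv.any():
        return []
    d = np.diff(inv.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if inv[0]:
        starts = np.concatenate([[0], starts])
    if inv[-1]:
        stops = np.concatenate([stops, [inv.size]])
    return list(zip(starts.tolist(), stops.tolist()))


def _valid_runs(valid: np.ndarray):
    return _invalid_runs(~valid)


def median_filter(gaze: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Running median of x and y over a centered window.

    Boundary samples with fewer than ``window`` neighbors are passed through
    unchanged (no shrinking window, no fabricated edge values). Timestamps,
    confidence and flags are untouched.
    """
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    out = gaze.copy()
    n = len(out)
    if window == 1 or n < window:
        return out
    half = window // 2
    for col in ("x", "y"):
        a = out[col].to_numpy(dtype=float)
        sw = np.lib.stride_tricks.sliding_window_view(a, window)
        filt = a.copy()
        filt[half : n - half] = np.median(sw, axis=1)
        out[col] = filt
    return out


def classify_gaps(gaze: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Mark low-confidence and off-screen samples as gaps.

    The comparison is strict: a sample at exactly the threshold is kept.
    Gap samples get ``valid=False`` and NaN coordinates.
    """
    out = gaze.copy()
    conf = out["confidence"].to_numpy(dtype=float)
    on = out["on_screen"].to_numpy(dtype=bool)
    finite = np.isfinite(out["x"].to_numpy(dtype=float)) & np.isfinite(
        out["y"].to_numpy(dtype=float)
    )
    valid = (conf >= threshold) & on & finite
    out["valid"] = valid
    out.loc[~valid, ["x", "y"]] = np.nan
    return out


def interpolate_short_gaps(gaze: pd.DataFrame, max_gap_ms: float = 75.0) -> pd.DataFrame:
    """Linearly fill gaps strictly shorter than ``max_gap_ms``.

    Gap duration is the time from the last valid sample before the run to the
    first valid sample after it; exact ties at the threshold are *not* filled.
    Runs touching either end of the stream are never filled.
    """
    out = gaze.copy()
    t = out["t"].to_numpy(dtype=float)
    valid = out["valid"].to_numpy(dtype=bool).copy()
    x = out["x"].to_numpy(dtype=float).copy()
    y = out["y"].to_numpy(dtype=float).copy()
    for i0, i1 in _invalid_runs(valid):
        if i0 == 0 or i1 == len(valid):
            continue
        ta, tb = t[i0 - 1], t[i1]
        if (tb - ta) * 1000.0 < max_gap_ms - 1e-6:
            seg = slice(i0, i1)
            x[seg] = np.interp(t[seg], [ta, tb], [x[i0 - 1], x[i1]])
            y[seg] = np.interp(t[seg], [ta, tb], [y[i0 - 1], y[i1]])
            valid[seg] = True
    out["x"], out["y"], out["valid"] = x, y, valid
    return out


def extend_gaps(gaze: pd.DataFrame, pad_ms: float = 100.0) -> pd.DataFrame:
    """Invalidate every sample within ``pad_ms`` (inclusive) of a gap.

    Applied after short-gap interpolation, so only genuine gaps (blinks,
    off-screen excursions) are dilated.
    """
    out = gaze.copy()
    t = out["t"].to_numpy(dtype=float)
    valid = out["valid"].to_numpy(dtype=bool)
    pad = pad_ms / 1000.0
    kill = np.zeros_like(valid)
    for i0, i1 in _invalid_runs(valid):
        lo = np.searchsorted(t, t[i0] - pad - _EPS_S, side="left")
        hi = np.searchsorted(t, t[i1 - 1] + pad + _EPS_S, side="right")
        kill[lo:hi] = True
    out.loc[kill, ["x", "y"]] = np.nan
    out.loc[kill, "valid"] = False
    return out


def resample_uniform(gaze: pd.DataFrame, rate_hz: float = 240.0) -> pd.DataFrame:
    """Resample to a uniform grid with monotone (PCHIP) cubic interpolation.

    The output grid runs from the first to the last input timestamp at
    ``rate_hz``. Each contiguous valid input segment is interpolated
    independently; grid points outside every valid segment (inside gaps, or in
    segments with fewer than two valid samples) are emitted invalid with NaN
    coordinates. Confidence and the on-screen flag are carried by
    nearest-neighbor lookup from the input stream.
    """
    t = gaze["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples to resample")
    n = int(np.floor((t[-1] - t[0]) * rate_hz + _EPS_S)) + 1
    grid = t[0] + np.arange(n) / rate_hz

    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    src_x = gaze["x"].to_numpy(dtype=float)
    src_y = gaze["y"].to_numpy(dtype=float)
    for i0, i1 in _valid_runs(gaze["valid"].to_numpy(dtype=bool)):
        if i1 - i0 < 2:
            continue
        ts = t[i0:i1]
        lo = np.searchsorted(grid, ts[0] - _EPS_S, side="left")
        hi = np.searchsorted(grid, ts[-1] + _EPS_S, side="right")
        if hi <= lo:
            continue
        g = grid[lo:hi]
        x[lo:hi] = PchipInterpolator(ts, src_x[i0:i1])(g)
        y[lo:hi] = PchipInterpolator(ts, src_y[i0:i1])(g)
        valid[lo:hi] = True

    # nearest-neighbor carry of per-sample metadata
    idx = np.clip(np.searchsorted(t, grid), 0, len(t) - 1)
    left = np.clip(idx - 1, 0, len(t) - 1)
    nearer_left = np.abs(grid - t[left]) <= np.abs(t[idx] - grid)
    nn = np.where(nearer_left, left, idx)
    return pd.DataFrame(
        {
            "t": grid,
            "x": x,
            "y": y,
            "confidence": gaze["confidence"].to_numpy(dtype=float)[nn],
            "on_screen": gaze["on_screen"].to_numpy(dtype=bool)[nn],
            "valid": valid,
        }
    )


def gap_stats(
    before: pd.DataFrame,
    after_classify: pd.DataFrame,
    after_interp: pd.DataFrame,
    after_pad: pd.DataFrame,
    threshold: float = 0.8,
) -> GapStats:
    """Percentages of gap samples at each preprocessing stage."""
    n = len(before)
    if not (len(after_classify) == len(after_interp) == len(after_pad) == n):
        raise ValueError("all four streams must share one timebase")
    if n == 0:
        return GapStats(0.0, 0.0, 0.0, 0.0, 0.0)

    def pct_invalid(df: pd.DataFrame) -> float:
        return 100.0 * float((~df["valid"].to_numpy(dtype=bool)).mean())

    conf = before["confidence"].to_numpy(dtype=float)
    on = before["on_screen"].to_numpy(dtype=bool)
    return GapStats(
        pct_low_confidence=100.0 * float((conf < threshold).mean()),
        pct_off_screen=100.0 * float((~on).mean()),
        pct_nan_before_interp=pct_invalid(after_classify),
        pct_nan_after_interp=pct_invalid(after_interp),
        pct_nan_after_pad=pct_invalid(after_pad),
    )


def preprocess_pipeline(
    gaze: pd.DataFrame, params: PreprocessParams = PreprocessParams()
) -> tuple[pd.DataFrame, GapStats]:
    """Run the full fixed-order pipeline; returns (resampled stream, stats)."""
    filtered = median_filter(gaze, params.median_window)
    classified = classify_gaps(filtered, params.confidence_threshold)
    interped = interpolate_short_gaps(classified, params.max_interp_gap_ms)
    padded = extend_gaps(interped, params.gap_pad_ms)
    stats = gap_stats(filtered, classified, interped, padded, params.confidence_threshold)
    resampled = resample_uniform(padded, params.target_rate_hz)
    return resampled, stats
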