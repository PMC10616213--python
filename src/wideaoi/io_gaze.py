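"""Reading and pooling per-surface gaze exports from a head-mounted tracker.

The eye-tracking software maps gaze onto fiducial-marker-delimited *surfaces*
and writes one CSV per surface with normalized within-surface coordinates, an
``on_surf`` flag and a pupil-detection ``confidence`` in [0, 1]. Because a
single surface spanning a 100-degree-wide display registers poorly, the display
is divided into nine narrow surfaces; this module pools the nine per-surface
streams back into one gaze stream in centered screen-pixel coordinates
((0, 0) at the display center, +y downward).

Within a surface, normalized coordinates follow the tracker's convention:
x_norm grows rightward from the left edge, y_norm grows *upward* from the
bottom edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SURFACE_EXPORT_COLUMNS",
    "SurfaceGazeRecord",
    "SurfaceLayout",
    "SyncReport",
    "read_surface_export",
    "pool_surfaces",
    "check_sync_markers",
    "worst_case_onset_latency_ms",
    "write_gaze_csv",
    "read_gaze_csv",
]

#: Required columns of a per-surface gaze export.
SURFACE_EXPORT_COLUMNS = (
    "gaze_timestamp",
    "world_index",
    "x_norm",
    "y_norm",
    "on_surf",
    "confidence",
)


@dataclass(frozen=True)
class SurfaceGazeRecord:
    """One row of a per-surface gaze export."""

    gaze_timestamp: float
    world_index: int
    x_norm: float
    y_norm: float
    on_surf: bool
    confidence: float


@dataclass(frozen=True)
class SurfaceLayout:
    """Axis-aligned partition of the display into surfaces.

    ``rects`` are ``(x0, y0, x1, y1)`` in top-left-origin display pixels,
    non-overlapping except for shared edges, covering the full display.
    """

    rects: tuple[tuple[float, float, float, float], ...]
    names: tuple[str, ...]
    width_px: int = 5760
    height_px: int = 1200

    def __post_init__(self) -> None:
        if len(self.rects) != len(self.names):
            raise ValueError("rects and names must have equal length")
        area = 0.0
        for x0, y0, x1, y1 in self.rects:
            if not (x0 < x1 and y0 < y1):
                raise ValueError("degenerate surface rectangle")
            area += (x1 - x0) * (y1 - y0)
        if abs(area - self.width_px * self.height_px) > 1e-6:
            raise ValueError("surfaces must tile the full display")

    @classmethod
    def default_grid(
        cls, width_px: int = 5760, height_px: int = 1200, n: int = 9
    ) -> "SurfaceLayout":
        """Nine full-height vertical strips, left to right."""
        edges = np.linspace(0, width_px, n + 1)
        rects = tuple(
            (float(edges[i]), 0.0, float(edges[i + 1]), float(height_px))
            for i in range(n)
        )
        names = tuple(f"surface{i}" for i in range(n))
        return cls(rects=rects, names=names, width_px=width_px, height_px=height_px)


@dataclass(frozen=True)
class SyncReport:
    """Per-scene timing check of the unique synchronization markers.

    ``discrepancies_ms[i] = (detected_onsets[i] - expected_onsets[i]) * 1000``;
    NaN marks a scene whose marker was never detected.
    """

    expected_onsets: tuple[float, ...]
    detected_onsets: tuple[float, ...]
    discrepancies_ms: tuple[float, ...]

    @property
    def worst_ms(self) -> float:
        finite = [abs(d) for d in self.discrepancies_ms if np.isfinite(d)]
        return max(finite) if finite else float("nan")


def worst_case_onset_latency_ms(world_fps: float = 30.0) -> int:
    """Worst-case marker-onset detection latency, whole milliseconds.

    The scene camera samples the display at ``world_fps``; a marker appearing
    just after a world frame is only seen one frame period later.
    """
    if world_fps <= 0:
        raise ValueError("world_fps must be positive")
    return int(1000.0 / world_fps)


def read_surface_export(path) -> pd.DataFrame:
    """Read one per-surface gaze export CSV.

    Returns a DataFrame with the :data:`SURFACE_EXPORT_COLUMNS` in file order.
    Malformed rows (unparseable numbers, confidence outside [0, 1], negative
    frame index, on-surface rows with non-finite coordinates) are skipped; the
    skip count is warned about and stored in ``df.attrs["skipped_rows"]``.

    Raises
    ------
    ValueError
        If a required column is missing from the header.
    """
    raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    for col in SURFACE_EXPORT_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"surface export {path!s} is missing column {col!r}")
    if raw.empty:
        warnings.warn(f"surface export {path!s} contains no data rows")
        df = pd.DataFrame(columns=list(SURFACE_EXPORT_COLUMNS))
        df.attrs["skipped_rows"] = 0
        return df

    out = pd.DataFrame(index=raw.index)
    for col in ("gaze_timestamp", "x_norm", "y_norm", "confidence"):
        out[col] = pd.to_numeric(raw[col], errors="coerce")
    out["world_index"] = pd.to_numeric(raw["world_index"], errors="coerce")
    on_surf = (
        raw["on_surf"].str.strip().str.lower().map(
            {"true": True, "1": True, "1.0": True, "false": False, "0": False, "0.0": False}
        )
    )
    out["on_surf"] = on_surf

    ok = (
        out["gaze_timestamp"].notna()
        & out["world_index"].notna()
        & (out["world_index"] >= 0)
        & out["confidence"].between(0.0, 1.0)
        & on_surf.notna()
    )
    # an on-surface record must carry usable coordinates
    ok &= ~on_surf.fillna(False) | (
        np.isfinite(out["x_norm"].to_numpy(dtype=float))
        & np.isfinite(out["y_norm"].to_numpy(dtype=float))
    )
    skipped = int((~ok).sum())
    if skipped:
        warnings.warn(f"surface export {path!s}: skipped {skipped} malformed row(s)")
    df = out.loc[ok, list(SURFACE_EXPORT_COLUMNS)].reset_index(drop=True)
    df["world_index"] = df["world_index"].astype(int)
    df["on_surf"] = df["on_surf"].astype(bool)
    df.attrs["skipped_rows"] = skipped
    return df


def _as_table(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [
            {
                "gaze_timestamp": r.gaze_timestamp,
                "world_index": r.world_index,
                "x_norm": r.x_norm,
                "y_norm": r.y_norm,
                "on_surf": r.on_surf,
                "confidence": r.confidence,
            }
            for r in records
        ],
        columns=list(SURFACE_EXPORT_COLUMNS),
    )


def pool_surfaces(per_surface, layout: SurfaceLayout, t0: float | None = None) -> pd.DataFrame:
    """Pool per-surface gaze streams into one centered-pixel gaze stream.

    Parameters
    ----------
    per_surface:
        Mapping from surface name to its export table (DataFrame or sequence
        of :class:`SurfaceGazeRecord`), or a sequence ordered like
        ``layout.names``. All streams must share one timestamp base.
    layout:
        The surface partition of the display.
    t0:
        Task start on the export timestamp base; defaults to the earliest
        timestamp seen. Output times are ``gaze_timestamp - t0``.

    Returns
    -------
    DataFrame with columns ``t, x, y, confidence, on_screen, valid``, one row
    per unique timestamp, time-ordered. For each timestamp the sample comes
    from a surface reporting ``on_surf``; among several, the surface whose
    normalized point lies deepest inside the unit square wins, ties broken by
    the lower surface index. With no on-surface record the sample is flagged
    off-screen and coordinates come from the least-out-of-bounds surface.
    """
    if len(layout.rects) != 9:
        raise ValueError(f"expected a 9-surface layout, got {len(layout.rects)}")
    if isinstance(per_surface, dict):
        tables = [_as_table(per_surface[name]) for name in layout.names]
    else:
        tables = [_as_table(t) for t in per_surface]
        if len(tables) != len(layout.names):
            raise ValueError("need one gaze table per surface")

    parts = []
    for i, tab in enumerate(tables):
        part = tab[["gaze_timestamp", "x_norm", "y_norm", "on_surf", "confidence"]].copy()
        part["surface"] = i
        parts.append(part)
    cat = pd.concat(parts, ignore_index=True)
    if cat.empty:
        return pd.DataFrame(columns=["t", "x", "y", "confidence", "on_screen", "valid"])

    xn = cat["x_norm"].to_numpy(dtype=float)
    yn = cat["y_norm"].to_numpy(dtype=float)
    depth = np.minimum.reduce([xn, 1.0 - xn, yn, 1.0 - yn])
    depth = np.where(np.isfinite(depth), depth, -np.inf)
    cat["depth"] = depth

    cat = cat.sort_values(
        ["gaze_timestamp", "on_surf", "depth", "surface"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = cat.groupby("gaze_timestamp", sort=True).first()
    any_on = cat.groupby("gaze_timestamp", sort=True)["on_surf"].any()

    rects = np.asarray(layout.rects, dtype=float)  # (n, 4): x0 y0 x1 y1
    sidx = best["surface"].to_numpy(dtype=int)
    x0, ytop, x1, ybot = (rects[sidx, k] for k in range(4))
    xn = best["x_norm"].to_numpy(dtype=float)
    yn = best["y_norm"].to_numpy(dtype=float)
    x_video = x0 + xn * (x1 - x0)
    y_video = ybot - yn * (ybot - ytop)  # y_norm grows upward within a surface

    ts = best.index.to_numpy(dtype=float)
    if t0 is None:
        t0 = float(ts[0])
    out = pd.DataFrame(
        {
            "t": ts - t0,
            "x": x_video - layout.width_px / 2.0,
            "y": y_video - layout.height_px / 2.0,
            "confidence": best["confidence"].to_numpy(dtype=float),
            "on_screen": any_on.to_numpy(dtype=bool),
            "valid": np.isfinite(x_video) & np.isfinite(y_video),
        }
    )
    return out.reset_index(drop=True)


def check_sync_markers(
    marker_records,
    expected_onsets,
    t0: float = 0.0,
    min_separation_s: float = 1.0,
) -> SyncReport:
    """Compare scheduled scene onsets with detected marker registrations.

    ``marker_records`` is the export of the dedicated synchronization surface:
    between scenes a unique fiducial marker is shown, so its registrations
    (``on_surf`` rows) arrive in well-separated clusters, one per scene.
    Clusters separated by more than ``min_separation_s`` are assigned to the
    scheduled scenes in order; a scene without a cluster gets NaN.
    """
    schedule = [float(v) for v in expected_onsets]
    if any(b <= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("expected_onsets must be strictly increasing")
    tab = _as_table(marker_records)
    reg = np.sort(tab.loc[tab["on_surf"].astype(bool), "gaze_timestamp"].to_numpy(dtype=float))
    onsets: list[float] = []
    if reg.size:
        breaks = np.flatnonzero(np.diff(reg) > min_separation_s)
        starts = np.concatenate([[0], breaks + 1])
        onsets = [float(reg[s]) - t0 for s in starts]
    detected = []
    discrepancies = []
    for i, exp in enumerate(schedule):
        if i < len(onsets):
            det = onsets[i]
            detected.append(det)
            discrepancies.append((det - exp) * 1000.0)
        else:
            detected.append(float("nan"))
            discrepancies.append(float("nan"))
            warnings.warn(f"sync marker for scene {i} (t={exp:g} s) never detected")
    return SyncReport(
        expected_onsets=tuple(schedule),
        detected_onsets=tuple(detected),
        discrepancies_ms=tuple(discrepancies),
    )


def write_gaze_csv(gaze: pd.DataFrame, path) -> None:
    """Write a pooled gaze stream (t, x, y, confidence, on_screen, valid)."""
    cols = ["t", "x", "y", "confidence", "on_screen", "valid"]
    gaze.loc[:, [c for c in cols if c in gaze.columns]].to_csv(path, index=False)


def read_gaze_csv(path) -> pd.DataFrame:
    gaze = pd.read_csv(path)
    for col in ("on_screen", "valid"):
        if col in gaze.columns:
            gaze[col] = gaze[col].astype(bool)
    if "valid" not in gaze.columns:
        gaze["valid"] = np.isfinite(gaze["x"]) & np.isfinite(gaze["y"])
    return gaze
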