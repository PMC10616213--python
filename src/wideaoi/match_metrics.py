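"""Frame-by-frame matching of gaze to dynamic AOIs and dwell/entry metrics.

Gaze is sampled at 240 Hz while the stimulus runs at 25 fps, so each gaze
sample is assigned to the video frame whose half-open interval
``[k/fps, (k+1)/fps)`` contains it, and tested against that frame's
(margin-expanded) AOI box. Runs of hit samples form *visits*; two cleaning
rules then mirror fixation physiology:

- an exit followed by a re-entry within less than 100 ms is treated as a
  precision artifact: the gap is pooled into the previous dwell, combining
  the two visits;
- a (merged) dwell still shorter than 100 ms cannot contain a fixation and is
  discarded.

From the retained visits, total dwell time, dwell percentage (of the object's
total appearance time), time to first entry and last exit time are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import AoiBox, AoiTrajectory
from .geometry import PixelMargins, ScreenGeometry, margins_for_edges

__all__ = [
    "MatchParams",
    "Visit",
    "AoiMetrics",
    "frame_of",
    "hit_test",
    "hit_mask",
    "extract_visits",
    "merge_and_filter",
    "summarize",
    "compute_metrics",
    "run_batch",
]

_EPS_S = 1e-9


@dataclass(frozen=True)
class MatchParams:
    """Matching parameters (defaults = validated setup)."""

    fps: float = 25.0
    min_intervisit_gap_ms: float = 100.0
    min_dwell_ms: float = 100.0

    def __post_init__(self) -> None:
        if min(self.fps, self.min_intervisit_gap_ms, self.min_dwell_ms) <= 0:
            raise ValueError("all matching parameters must be positive")


@dataclass(frozen=True)
class Visit:
    """One entry-to-exit interval inside an AOI, at sample timestamps.

    A single-sample visit has ``t_exit == t_entry``; such zero-length visits
    are always removed by the minimum-dwell filter.
    """

    t_entry: float
    t_exit: float

    def __post_init__(self) -> None:
        if self.t_exit < self.t_entry:
            raise ValueError("t_exit must be >= t_entry")

    @property
    def duration_s(self) -> float:
        return self.t_exit - self.t_entry


@dataclass(frozen=True)
class AoiMetrics:
    """Dwell/entry summary for one object (one participant, one margin)."""

    object_id: str
    total_dwell_s: float
    dwell_pct: float
    time_to_first_entry_s: float  # NaN when the AOI was never entered
    t_last_exit_s: float  # NaN when the AOI was never entered
    n_visits: int
    appearance_s: float


def frame_of(t, fps: float = 25.0, t0: float = 0.0):
    """Video frame index containing time ``t`` (half-open frame intervals)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < t0 - _EPS_S):
        raise ValueError("sample time precedes the video start")
    f = np.floor((t - t0) * fps + _EPS_S).astype(int)
    return f if f.shape else int(f)


def hit_test(sample, box: AoiBox, margins: PixelMargins) -> bool:
    """Whether a valid gaze sample lies in the margin-expanded box (closed)."""
    if not bool(sample.valid):
        raise ValueError("hit_test requires a valid (non-gap) sample")
    return bool(
        box.x_left - margins.left_px <= sample.x <= box.x_right + margins.right_px
        and box.y_top - margins.top_px <= sample.y <= box.y_bottom + margins.bottom_px
    )


def _expanded_edges(traj: AoiTrajectory, margin_deg: float, geom: ScreenGeometry):
    """Per-frame margin-expanded box edges for one trajectory."""
    xl = traj.table["x_left"].to_numpy(dtype=float)
    xr = traj.table["x_right"].to_numpy(dtype=float)
    yt = traj.table["y_top"].to_numpy(dtype=float)
    yb = traj.table["y_bottom"].to_numpy(dtype=float)
    left, right, vert = margins_for_edges(xl, xr, (yt + yb) / 2.0, margin_deg, geom)
    return xl - left, xr + right, yt - vert, yb + vert


def hit_mask(
    gaze: pd.DataFrame,
    traj: AoiTrajectory,
    margin_deg: float,
    geom: ScreenGeometry,
    params: MatchParams = MatchParams(),
) -> np.ndarray:
    """Boolean per-sample AOI hit (False outside the AOI lifetime or in gaps).

    Margins are computed frame-by-frame: the left and right expansions use the
    eccentricity of the respective box edge, the vertical expansion the box
    center's y eccentricity, so boxes near the display edges get wider pixel
    margins for the same visual angle.
    """
    t = gaze["t"].to_numpy(dtype=float)
    x = gaze["x"].to_numpy(dtype=float)
    y = gaze["y"].to_numpy(dtype=float)
    valid = gaze["valid"].to_numpy(dtype=bool)

    f = frame_of(t, params.fps)
    in_life = (f >= traj.first_frame) & (f <= traj.last_frame)
    exl, exr, eyt, eyb = _expanded_edges(traj, margin_deg, geom)

    hit = np.zeros(len(gaze), dtype=bool)
    sel = in_life & valid & np.isfinite(x) & np.isfinite(y)
    idx = f[sel] - traj.first_frame
    hit[sel] = (
        (x[sel] >= exl[idx])
        & (x[sel] <= exr[idx])
        & (y[sel] >= eyt[idx])
        & (y[sel] <= eyb[idx])
    )
    return hit


def extract_visits(t, hits, valid=None) -> list[Visit]:
    """Runs of consecutive hit samples as visits.

    A visit opens at the first hit after a non-hit (or the stream start) and
    closes at the last hit before a non-hit (or the stream end); gap samples
    end a visit exactly like non-hits. Entry and exit times are the opening
    and closing sample timestamps.
    """
    t = np.asarray(t, dtype=float)
    hits = np.asarray(hits, dtype=bool)
    if valid is not None:
        hits = hits & np.asarray(valid, dtype=bool)
    if len(t) != len(hits):
        raise ValueError("timestamps and hit flags must align")
    visits = []
    padded = np.concatenate([[False], hits, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    for i0, i1 in zip(starts, stops):
        visits.append(Visit(t_entry=float(t[i0]), t_exit=float(t[i1 - 1])))
    return visits


def merge_and_filter(visits, params: MatchParams = MatchParams()) -> list[Visit]:
    """Apply the 100 ms merge rule, then the 100 ms minimum-dwell rule.

    Left-to-right pass: while the out-of-AOI gap to the next visit is shorter
    than ``min_intervisit_gap_ms``, the gap time is pooled into the previous
    dwell and the visits combine. Afterwards, merged visits still shorter than
    ``min_dwell_ms`` are dropped.
    """
    visits = sorted(visits, key=lambda v: v.t_entry)
    for a, b in zip(visits, visits[1:]):
        if b.t_entry < a.t_exit:
            raise ValueError("visits must not overlap")
    merged: list[Visit] = []
    for v in visits:
        if merged and (v.t_entry - merged[-1].t_exit) * 1000.0 < (
            params.min_intervisit_gap_ms - 1e-6
        ):
            merged[-1] = Visit(merged[-1].t_entry, v.t_exit)
        else:
            merged.append(v)
    return [
        v for v in merged if v.duration_s * 1000.0 >= params.min_dwell_ms - 1e-6
    ]


def summarize(
    visits,
    traj: AoiTrajectory,
    params: MatchParams = MatchParams(),
) -> AoiMetrics:
    """Dwell/entry metrics from retained visits and the AOI's visibility.

    The appearance time is the closed frame range of the trajectory,
    ``(last - first + 1) / fps``; time to first entry is measured from the
    object's first appearance to the entry of the first *retained* visit.
    The dwell percentage is reported uncapped (a warning is emitted if the
    pad/merge arithmetic pushes it past 100%).
    """
    visits = sorted(visits, key=lambda v: v.t_entry)
    appearance = traj.duration_s(params.fps)
    t_appear = traj.first_frame / params.fps
    total = float(sum(v.duration_s for v in visits))
    pct = 100.0 * total / appearance
    if pct > 100.0 + 1e-9:
        warnings.warn(
            f"dwell percentage {pct:.2f}% exceeds 100% for {traj.object_id!r} "
            "(merge/pad arithmetic); reported uncapped"
        )
    return AoiMetrics(
        object_id=traj.object_id,
        total_dwell_s=total,
        dwell_pct=pct,
        time_to_first_entry_s=(visits[0].t_entry - t_appear) if visits else float("nan"),
        t_last_exit_s=visits[-1].t_exit if visits else float("nan"),
        n_visits=len(visits),
        appearance_s=appearance,
    )


def compute_metrics(
    gaze: pd.DataFrame,
    traj: AoiTrajectory,
    margin_deg: float,
    geom: ScreenGeometry,
    params: MatchParams = MatchParams(),
) -> AoiMetrics:
    """Full match for one (gaze stream, object, margin): hits to metrics."""
    hits = hit_mask(gaze, traj, margin_deg, geom, params)
    raw = extract_visits(gaze["t"].to_numpy(dtype=float), hits)
    kept = merge_and_filter(raw, params)
    return summarize(kept, traj, params)


def run_batch(
    gaze_streams,
    trajectories,
    margins_deg,
    geom: ScreenGeometry,
    params: MatchParams = MatchParams(),
) -> pd.DataFrame:
    """Long-format metrics table over participants x objects x margins.

    ``gaze_streams`` maps participant id to a preprocessed gaze DataFrame.
    Output has one row per (participant, object_id, margin_deg), sorted, with
    all :class:`AoiMetrics` fields. An empty gaze stream yields NaN metrics
    for that participant (logged via a warning).
    """
    rows = []
    for participant in sorted(gaze_streams):
        gaze = gaze_streams[participant]
        for traj in sorted(trajectories, key=lambda tr: tr.object_id):
            for margin in margins_deg:
                if len(gaze) == 0:
                    warnings.warn(
                        f"empty gaze stream for participant {participant!r}; "
                        f"metrics missing for {traj.object_id!r}"
                    )
                    metrics = AoiMetrics(
                        traj.object_id,
                        float("nan"),
                        float("nan"),
                        float("nan"),
                        float("nan"),
                        0,
                        traj.duration_s(params.fps),
                    )
                else:
                    metrics = compute_metrics(gaze, traj, margin, geom, params)
                rows.append(
                    {
                        "participant": participant,
                        "object_id": traj.object_id,
                        "margin_deg": margin,
                        "total_dwell_s": metrics.total_dwell_s,
                        "dwell_pct": metrics.dwell_pct,
                        "time_to_first_entry_s": metrics.time_to_first_entry_s,
                        "t_last_exit_s": metrics.t_last_exit_s,
                        "n_visits": metrics.n_visits,
                        "appearance_s": metrics.appearance_s,
                    }
                )
    return pd.DataFrame(rows)
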