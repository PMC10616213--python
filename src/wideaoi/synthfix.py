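"""Fully synthetic, ground-truthed fixtures for the whole analysis chain.

A :class:`ScenarioScript` describes a recording session the way the real setup
produces one: scripted rectangular objects moving across the 5760x1200 display,
a gaze signal that pursues them (with optional pursuit lag, Gaussian angular
noise, blinks and off-screen excursions), and the two 120 Hz eye cameras
sampling in anti-phase so the merged stream runs at an effective 240 Hz.
:func:`generate_scenario` renders that script into the same artifacts the
recording pipeline exports — nine per-surface gaze CSV tables, an AOI table,
optionally video frames — plus a :class:`GroundTruth` with the exact visit
intervals and metrics the default pipeline should recover.

Angular noise is applied in degrees and projected to pixels through the
flat-screen tangent model, so pixel noise grows toward the display periphery
like real eye-tracking error does. An optional eccentricity gain additionally
scales noise (and can push samples off-screen) at large angles to emulate the
accuracy loss seen at 40-50 degrees.

Everything is driven by one integer seed; a fixed seed yields byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AoiTrajectory
from .geometry import ScreenGeometry, deg_to_px, px_to_deg
from .io_gaze import SurfaceLayout
from .match_metrics import MatchParams
from .preprocess import PreprocessParams

__all__ = [
    "ObjectScript",
    "TargetSegment",
    "ScenarioScript",
    "GroundTruth",
    "ScenarioData",
    "generate_scenario",
    "expected_metrics",
    "render_frames",
    "write_scenario",
    "tracking_scenario",
    "noisy_scenario",
]

_WORLD_FPS = 30.0  # scene-camera rate of the recording glasses


@dataclass(frozen=True)
class ObjectScript:
    """One scripted rectangular object: linear/parabolic path plus size ramp.

    Positions are the box *center* in centered display pixels; the box is
    visible on the closed frame range covering [t_start, t_end).
    """

    object_id: str
    t_start: float
    t_end: float
    x_start: float
    y_start: float
    x_end: float
    y_end: float
    width_start: float
    height_start: float
    width_end: float | None = None
    height_end: float | None = None
    path: str = "linear"  # "linear" | "parabolic"
    curvature_px: float = 0.0  # peak vertical deflection for parabolic paths
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("object must be visible for a positive duration")
        if self.path not in ("linear", "parabolic"):
            raise ValueError("path must be 'linear' or 'parabolic'")

    def _s(self, t) -> np.ndarray:
        span = self.t_end - self.t_start
        return np.clip((np.asarray(t, dtype=float) - self.t_start) / span, 0.0, 1.0)

    def center_at(self, t):
        s = self._s(t)
        x = self.x_start + s * (self.x_end - self.x_start)
        y = self.y_start + s * (self.y_end - self.y_start)
        if self.path == "parabolic":
            y = y + 4.0 * self.curvature_px * s * (1.0 - s)
        return x, y

    def size_at(self, t):
        s = self._s(t)
        w_end = self.width_start if self.width_end is None else self.width_end
        h_end = self.height_start if self.height_end is None else self.height_end
        return (
            self.width_start + s * (w_end - self.width_start),
            self.height_start + s * (h_end - self.height_start),
        )


@dataclass(frozen=True)
class TargetSegment:
    """What the scripted gaze looks at during [t_start, t_end).

    Either an ``object_id`` (smooth pursuit of that object's center) or a
    fixed ``fixation`` point in centered pixels.
    """

    t_start: float
    t_end: float
    object_id: str | None = None
    fixation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.object_id is None) == (self.fixation is None):
            raise ValueError("segment needs exactly one of object_id / fixation")


@dataclass(frozen=True)
class ScenarioScript:
    """Complete description of one synthetic recording."""

    duration_s: float
    objects: tuple[ObjectScript, ...]
    targets: tuple[TargetSegment, ...]
    fps: float = 25.0
    eye_rate_hz: float = 120.0
    pursuit_lag_ms: float = 0.0
    noise_sigma_deg: float = 0.0
    accuracy_offset_deg: tuple[float, float] = (0.0, 0.0)  # calibration bias (x, y)
    eccentric_noise_gain: float = 0.0
    eccentric_offscreen_gain: float = 0.0
    blinks: tuple[tuple[float, float], ...] = ()  # (onset_s, duration_s)
    off_screen: tuple[tuple[float, float], ...] = ()  # (t_start, t_end)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_deg < 0:
            raise ValueError("noise_sigma_deg must be >= 0")
        for onset, dur in self.blinks:
            if not (0 <= onset and onset + dur <= self.duration_s):
                raise ValueError("blink outside the scenario duration")
        for a, b in self.off_screen:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError("off-screen interval outside the scenario duration")


@dataclass
class GroundTruth:
    """Exact expected pipeline output, from interval arithmetic on the script.

    ``per_object[object_id]`` holds the expected visit intervals and metrics
    under the default parameters, assuming the scripted gaze lands inside the
    AOI whenever it pursues the object (exact for noiseless, lag-free scripts;
    a qualitative reference otherwise).
    """

    per_object: dict
    gap_spans: list


@dataclass
class ScenarioData:
    """Everything one scenario produces."""

    script: ScenarioScript
    layout: SurfaceLayout
    geom: ScreenGeometry
    surfaces: dict  # surface name -> per-surface export DataFrame
    trajectories: list
    aoi_table: pd.DataFrame
    gaze_truth: pd.DataFrame  # t, x_true, y_true, blink, off_screen
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# interval helpers (continuous time, used only for ground truth)


def _union(intervals):
    out = []
    for a, b in sorted(i for i in intervals if i[1] > i[0]):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _intersect_one(intervals, lo, hi):
    return [(max(a, lo), min(b, hi)) for a, b in intervals if min(b, hi) > max(a, lo)]


def _subtract(intervals, gaps):
    out = []
    for a, b in intervals:
        cur = a
        for g0, g1 in gaps:
            if g1 <= cur or g0 >= b:
                continue
            if g0 > cur:
                out.append((cur, g0))
            cur = max(cur, g1)
            if cur >= b:
                break
        if cur < b:
            out.append((cur, b))
    return out


def _merge_filter_intervals(visits, params: MatchParams):
    merged = []
    for v in sorted(visits):
        if merged and (v[0] - merged[-1][1]) * 1000.0 < params.min_intervisit_gap_ms - 1e-9:
            merged[-1] = (merged[-1][0], v[1])
        else:
            merged.append(v)
    return [v for v in merged if (v[1] - v[0]) * 1000.0 >= params.min_dwell_ms - 1e-9]


def expected_metrics(
    script: ScenarioScript,
    pre: PreprocessParams = PreprocessParams(),
    match: MatchParams = MatchParams(),
) -> GroundTruth:
    """Ground-truth visits and metrics by direct interval arithmetic.

    Gap spans are the scripted blinks of at least the interpolation limit
    (shorter ones are bridged by the pipeline) and all off-screen excursions,
    each dilated by the gap pad; visits are the pursuit intervals inside the
    AOI lifetime minus those spans, run through the same merge/minimum-dwell
    rules the matcher applies.
    """
    pad = pre.gap_pad_ms / 1000.0
    gaps = []
    for onset, dur in script.blinks:
        if dur * 1000.0 >= pre.max_interp_gap_ms - 1e-9:
            gaps.append((onset - pad, onset + dur + pad))
    for a, b in script.off_screen:
        if (b - a) * 1000.0 >= pre.max_interp_gap_ms - 1e-9:
            gaps.append((a - pad, b + pad))
    gaps = _union(gaps)

    per_object = {}
    for obj in script.objects:
        first_frame = int(round(obj.t_start * script.fps))
        last_frame = int(round(obj.t_end * script.fps)) - 1
        t_appear = first_frame / script.fps
        t_gone = (last_frame + 1) / script.fps
        appearance = t_gone - t_appear
        pursued = _union(
            [
                (seg.t_start, seg.t_end)
                for seg in script.targets
                if seg.object_id == obj.object_id
            ]
        )
        candidate = _intersect_one(pursued, t_appear, t_gone)
        visits = _merge_filter_intervals(_subtract(candidate, gaps), match)
        total = sum(b - a for a, b in visits)
        per_object[obj.object_id] = {
            "expected_visits": visits,
            "appearance_s": appearance,
            "total_dwell_s": total,
            "dwell_pct": 100.0 * total / appearance,
            "time_to_first_entry_s": (visits[0][0] - t_appear) if visits else float("nan"),
            "n_visits": len(visits),
        }
    return GroundTruth(per_object=per_object, gap_spans=gaps)


# ---------------------------------------------------------------------------
# scenario synthesis


def _object_trajectory(obj: ObjectScript, script: ScenarioScript, geom: ScreenGeometry):
    first = int(round(obj.t_start * script.fps))
    last = int(round(obj.t_end * script.fps)) - 1
    frames = np.arange(first, last + 1)
    t = frames / script.fps
    cx, cy = obj.center_at(t)
    w, h = obj.size_at(t)
    xl = np.rint(cx - w / 2).astype(int)
    xr = np.rint(cx + w / 2).astype(int)
    yt = np.rint(cy - h / 2).astype(int)
    yb = np.rint(cy + h / 2).astype(int)
    half_w, half_h = geom.width_px / 2, geom.height_px / 2
    if (xl < -half_w).any() or (xr > half_w).any() or (yt < -half_h).any() or (yb > half_h).any():
        raise ValueError(
            f"object {obj.object_id!r} leaves the display; script an off-screen "
            "interval instead of moving the box outside"
        )
    table = pd.DataFrame(
        {"frame": frames, "x_left": xl, "y_top": yt, "x_right": xr, "y_bottom": yb}
    )
    table["label"] = obj.label
    return AoiTrajectory(object_id=obj.object_id, table=table)


def _gaze_positions(script: ScenarioScript, t: np.ndarray):
    """Noise-free pursued position per sample (centered pixels)."""
    by_id = {o.object_id: o for o in script.objects}
    lag = script.pursuit_lag_ms / 1000.0
    x = np.zeros_like(t)
    y = np.zeros_like(t)
    for seg in script.targets:
        sel = (t >= seg.t_start) & (t < seg.t_end)
        if not sel.any():
            continue
        if seg.object_id is not None:
            cx, cy = by_id[seg.object_id].center_at(t[sel] - lag)
        else:
            cx, cy = seg.fixation
        x[sel] = cx
        y[sel] = cy
    return x, y


def generate_scenario(
    script: ScenarioScript,
    geom: ScreenGeometry | None = None,
    layout: SurfaceLayout | None = None,
) -> ScenarioData:
    """Render a script into per-surface exports, AOI table and ground truth."""
    geom = geom or ScreenGeometry()
    layout = layout or SurfaceLayout.default_grid(geom.width_px, geom.height_px)
    rng = np.random.default_rng(script.seed)

    # two eye cameras in anti-phase -> effective double-rate merged stream
    period = 1.0 / script.eye_rate_hz
    n_eye = int(np.floor(script.duration_s * script.eye_rate_hz))
    eye0 = np.arange(n_eye) * period
    eye1 = eye0 + period / 2.0
    t = np.sort(np.concatenate([eye0, eye1[eye1 < script.duration_s]]))

    x, y = _gaze_positions(script, t)

    off_x, off_y = script.accuracy_offset_deg
    if script.noise_sigma_deg > 0 or script.eccentric_noise_gain > 0 or off_x or off_y:
        theta_x = px_to_deg(x, geom)
        theta_y = px_to_deg(y, geom)
        sigma = script.noise_sigma_deg * (
            1.0 + script.eccentric_noise_gain * np.abs(theta_x) / 50.0
        )
        theta_x = np.clip(
            theta_x + off_x + rng.normal(0.0, 1.0, t.size) * sigma, -89.0, 89.0
        )
        theta_y = np.clip(
            theta_y + off_y + rng.normal(0.0, 1.0, t.size) * sigma, -89.0, 89.0
        )
        x = deg_to_px(theta_x, geom)
        y = deg_to_px(theta_y, geom)

    off = np.zeros(t.size, dtype=bool)
    for a, b in script.off_screen:
        off |= (t >= a) & (t < b)
    if script.eccentric_offscreen_gain > 0:
        p = script.eccentric_offscreen_gain * (np.abs(px_to_deg(x, geom)) / 50.0) ** 2
        off |= rng.random(t.size) < p
    x = np.where(off, geom.width_px / 2.0 + 150.0, x)

    blink = np.zeros(t.size, dtype=bool)
    for onset, dur in script.blinks:
        blink |= (t >= onset) & (t < onset + dur)
    confidence = 0.90 + 0.08 * rng.random(t.size)
    confidence[blink] = 0.2 + 0.3 * rng.random(int(blink.sum()))

    # per-surface export tables (tracker dialect; y_norm grows upward)
    x_video = x + geom.width_px / 2.0
    y_video = y + geom.height_px / 2.0
    world_index = np.floor(t * _WORLD_FPS + 1e-9).astype(int)
    surfaces = {}
    for name, (x0, ytop, x1, ybot) in zip(layout.names, layout.rects):
        xn = (x_video - x0) / (x1 - x0)
        yn = (ybot - y_video) / (ybot - ytop)
        on_surf = (xn >= 0) & (xn <= 1) & (yn >= 0) & (yn <= 1) & ~off
        surfaces[name] = pd.DataFrame(
            {
                "world_timestamp": world_index / _WORLD_FPS,
                "world_index": world_index,
                "gaze_timestamp": t,
                "x_norm": xn,
                "y_norm": yn,
                "x_scaled": xn * (x1 - x0),
                "y_scaled": yn * (ybot - ytop),
                "on_surf": on_surf,
                "confidence": confidence,
            }
        )

    trajectories = [_object_trajectory(obj, script, geom) for obj in script.objects]
    parts = []
    for traj in trajectories:
        part = traj.table.copy()
        part["object_id"] = traj.object_id
        parts.append(part)
    aoi_table = pd.concat(parts, ignore_index=True)

    gaze_truth = pd.DataFrame(
        {"t": t, "x_true": x, "y_true": y, "blink": blink, "off_screen": off}
    )
    return ScenarioData(
        script=script,
        layout=layout,
        geom=geom,
        surfaces=surfaces,
        trajectories=trajectories,
        aoi_table=aoi_table,
        gaze_truth=gaze_truth,
        ground_truth=expected_metrics(script),
    )


def render_frames(
    script: ScenarioScript, geom: ScreenGeometry | None = None, scale: float = 0.1
) -> np.ndarray:
    """Simple synthetic stimulus frames: filled object rectangles on gray.

    ``scale`` shrinks the display resolution (full 5760x1200 frames are
    rarely needed for testing). Returns a uint8 RGB stack
    ``(n_frames, H, W, 3)``.
    """
    geom = geom or ScreenGeometry()
    h = max(int(round(geom.height_px * scale)), 8)
    w = max(int(round(geom.width_px * scale)), 8)
    n = int(round(script.duration_s * script.fps))
    stack = np.full((n, h, w, 3), 40, dtype=np.uint8)
    for i, obj in enumerate(script.objects):
        shade = 140 + (40 * i) % 110
        first = int(round(obj.t_start * script.fps))
        last = min(int(round(obj.t_end * script.fps)) - 1, n - 1)
        for f in range(first, last + 1):
            tt = f / script.fps
            cx, cy = obj.center_at(tt)
            bw, bh = obj.size_at(tt)
            c0 = int(round((cx - bw / 2 + geom.width_px / 2) * scale))
            c1 = int(round((cx + bw / 2 + geom.width_px / 2) * scale))
            r0 = int(round((cy - bh / 2 + geom.height_px / 2) * scale))
            r1 = int(round((cy + bh / 2 + geom.height_px / 2) * scale))
            stack[f, max(r0, 0) : max(r1, 0), max(c0, 0) : max(c1, 0)] = shade
    return stack


def write_scenario(data: ScenarioData, out_dir) -> None:
    """Write the scenario artifacts as plain-text files.

    One CSV per surface (tracker export dialect), the AOI table, the true
    gaze trace, and the ground-truth metrics as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in data.surfaces.items():
        table.to_csv(out / f"gaze_positions_on_surface_{name}.csv", index=False)
    data.aoi_table.to_csv(out / "aois.csv", index=False)
    data.gaze_truth.to_csv(out / "gaze_truth.csv", index=False)
    truth = {
        "gap_spans": data.ground_truth.gap_spans,
        "per_object": data.ground_truth.per_object,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# canonical scenarios


def tracking_scenario(
    blinks: tuple[tuple[float, float], ...] = (),
    duration_s: float = 10.5,
    noise_sigma_deg: float = 0.0,
    pursuit_lag_ms: float = 0.0,
    seed: int = 0,
) -> ScenarioScript:
    """One object visible for 10 s, pursued for the whole scenario.

    The blink-free, noiseless default is the exact-recovery reference: the
    pipeline should report a dwell percentage of 100 and zero time to first
    entry. Blink onsets, when supplied, should avoid the 240 Hz sample grid so
    boundary losses stay below one sample period. The object disappears half a
    second before the scenario ends, so the gaze stream always outlives the
    AOI (the default: a 10 s AOI in a 10.5 s recording).
    """
    obj = ObjectScript(
        object_id="target",
        t_start=0.0,
        t_end=duration_s - 0.5,
        x_start=-600.0,
        y_start=-100.0,
        x_end=600.0,
        y_end=100.0,
        width_start=140.0,
        height_start=140.0,
        width_end=200.0,
        height_end=200.0,
    )
    return ScenarioScript(
        duration_s=duration_s,
        objects=(obj,),
        targets=(TargetSegment(0.0, duration_s, object_id="target"),),
        noise_sigma_deg=noise_sigma_deg,
        pursuit_lag_ms=pursuit_lag_ms,
        blinks=blinks,
        seed=seed,
    )


#: Blink schedule for the scripted three-blink variant: 200 ms each, onsets
#: off the 240 Hz grid.
THREE_BLINKS: tuple[tuple[float, float], ...] = (
    (2.0005, 0.2),
    (5.0005, 0.2),
    (8.0005, 0.2),
)


def noisy_scenario(seed: int = 0, noise_sigma_deg: float = 0.5) -> ScenarioScript:
    """Three objects of varied size/eccentricity with imperfect pursuit.

    The gaze carries a constant 0.9-degree calibration offset (the order of
    accuracy a head-mounted tracker delivers on a wide screen), 0.5 degrees of
    per-sample angular noise, 80 ms pursuit lag and two blinks. With that
    inaccuracy many samples fall just outside the raw boxes, so growing the
    visual-angle margin must monotonically recover dwell percentage — the
    margin exists precisely to compensate calibration inaccuracy.
    """
    objects = (
        ObjectScript(
            "car", 0.0, 10.0, -2000.0, -200.0, 2000.0, -100.0, 150.0, 150.0, 220.0, 220.0
        ),
        ObjectScript(
            "cyclist", 2.0, 9.0, 2400.0, 150.0, 1200.0, 100.0, 120.0, 180.0
        ),
        ObjectScript(
            "sign", 1.0, 8.0, -2500.0, 0.0, -2500.0, 0.0, 100.0, 100.0
        ),
    )
    targets = (
        TargetSegment(0.0, 3.5, object_id="car"),
        TargetSegment(3.5, 6.5, object_id="cyclist"),
        TargetSegment(6.5, 8.0, object_id="sign"),
        TargetSegment(8.0, 10.5, object_id="car"),
    )
    return ScenarioScript(
        duration_s=10.5,
        objects=objects,
        targets=targets,
        noise_sigma_deg=noise_sigma_deg,
        accuracy_offset_deg=(1.0, -0.8),
        pursuit_lag_ms=80.0,
        blinks=((1.5, 0.15), (5.2, 0.18)),
        seed=seed,
    )
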