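"""Per-frame AOI bounding boxes: tracking, keyframe interpolation, table I/O.

Dynamic areas of interest are axis-aligned rectangles, one box per video frame
per object, in *centered* display pixels ((0, 0) at the display center, +y
downward). Frame indices are 0-based and an object's visibility interval is the
closed frame range [first_frame, last_frame].

Three routes produce trajectories:

- :func:`track_object` follows an object semi-automatically from an initial
  box using multi-scale normalized cross-correlation of the previous frame's
  box content against a local search window, adapting the box size to the
  object's apparent size. It halts with status ``"lost"`` when the correlation
  peak drops below a threshold (typical when an object grows to cover much of
  the scene); keyframe corrections can override or resume it.
- :func:`interpolate_boxes` blends box edges linearly between drawn keyframes.
- Fully manual tables can be written directly in the CSV schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import match_template
from skimage.transform import resize

from .geometry import ScreenGeometry

__all__ = [
    "AoiBox",
    "AoiTrajectory",
    "TrackResult",
    "track_object",
    "interpolate_boxes",
    "write_aoi_table",
    "read_aoi_table",
    "trajectory_summary",
    "iou",
]

AOI_TABLE_COLUMNS = ("frame", "x_left", "y_top", "x_right", "y_bottom", "object_id", "label")


@dataclass(frozen=True)
class AoiBox:
    """One object's bounding box on one video frame (centered pixels)."""

    frame: int
    x_left: float
    y_top: float
    x_right: float
    y_bottom: float
    object_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame index must be >= 0")
        if not (self.x_left < self.x_right and self.y_top < self.y_bottom):
            raise ValueError("box must satisfy x_left < x_right and y_top < y_bottom")

    @property
    def width(self) -> float:
        return self.x_right - self.x_left

    @property
    def height(self) -> float:
        return self.y_bottom - self.y_top

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_left + self.x_right) / 2.0, (self.y_top + self.y_bottom) / 2.0)


@dataclass
class AoiTrajectory:
    """Frame-contiguous sequence of boxes for one object.

    ``table`` has one row per frame over [first_frame, last_frame] with
    columns frame, x_left, y_top, x_right, y_bottom, label.
    """

    object_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        frames = self.table["frame"].to_numpy(dtype=int)
        if len(frames) == 0:
            raise ValueError("trajectory must contain at least one box")
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise ValueError("trajectory boxes must be frame-contiguous")
        bad = (self.table["x_left"] >= self.table["x_right"]) | (
            self.table["y_top"] >= self.table["y_bottom"]
        )
        if bad.any():
            raise ValueError("degenerate box in trajectory")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_boxes(cls, boxes) -> "AoiTrajectory":
        boxes = sorted(boxes, key=lambda b: b.frame)
        table = pd.DataFrame(
            {
                "frame": [b.frame for b in boxes],
                "x_left": [b.x_left for b in boxes],
                "y_top": [b.y_top for b in boxes],
                "x_right": [b.x_right for b in boxes],
                "y_bottom": [b.y_bottom for b in boxes],
                "label": [b.label for b in boxes],
            }
        )
        object_id = boxes[0].object_id if boxes else ""
        return cls(object_id=object_id, table=table)

    @property
    def first_frame(self) -> int:
        return int(self.table["frame"].iloc[0])

    @property
    def last_frame(self) -> int:
        return int(self.table["frame"].iloc[-1])

    def duration_s(self, fps: float = 25.0) -> float:
        return (self.last_frame - self.first_frame + 1) / fps

    def box_at(self, frame: int) -> AoiBox:
        if not self.first_frame <= frame <= self.last_frame:
            raise KeyError(f"frame {frame} outside [{self.first_frame}, {self.last_frame}]")
        row = self.table.iloc[frame - self.first_frame]
        return AoiBox(
            frame=int(row["frame"]),
            x_left=float(row["x_left"]),
            y_top=float(row["y_top"]),
            x_right=float(row["x_right"]),
            y_bottom=float(row["y_bottom"]),
            object_id=self.object_id,
            label=str(row.get("label", "")),
        )


def iou(a: AoiBox, b: AoiBox) -> float:
    """Intersection-over-union of two boxes (frame indices ignored)."""
    ix = max(0.0, min(a.x_right, b.x_right) - max(a.x_left, b.x_left))
    iy = max(0.0, min(a.y_bottom, b.y_bottom) - max(a.y_top, b.y_top))
    inter = ix * iy
    union = a.width * a.height + b.width * b.height - inter
    return inter / union if union > 0 else 0.0


def interpolate_boxes(keyframes) -> AoiTrajectory:
    """Linearly interpolate box edges between drawn keyframes.

    Keyframes must be for one object with strictly increasing frame numbers;
    interior boxes are the per-edge affine blend, rounded to the nearest
    integer pixel, and keyframes are reproduced exactly.
    """
    keyframes = list(keyframes)
    if len(keyframes) < 2:
        raise ValueError("need at least two keyframes to interpolate")
    frames = [b.frame for b in keyframes]
    if len(set(frames)) != len(frames):
        raise ValueError("duplicate keyframe frame numbers")
    if frames != sorted(frames):
        raise ValueError("keyframes must be strictly increasing in frame")
    kf = np.asarray(frames, dtype=float)
    out_frames = np.arange(frames[0], frames[-1] + 1)
    cols = {}
    for name in ("x_left", "y_top", "x_right", "y_bottom"):
        vals = np.asarray([getattr(b, name) for b in keyframes], dtype=float)
        cols[name] = np.rint(np.interp(out_frames, kf, vals)).astype(int)
    table = pd.DataFrame({"frame": out_frames, **cols})
    table["label"] = keyframes[0].label
    return AoiTrajectory(object_id=keyframes[0].object_id, table=table)


def write_aoi_table(trajectories, path) -> None:
    """Serialize trajectories to the AOI CSV schema (centered coordinates)."""
    parts = []
    for traj in trajectories:
        part = traj.table.copy()
        part["object_id"] = traj.object_id
        if "label" not in part.columns:
            part["label"] = ""
        parts.append(part[list(AOI_TABLE_COLUMNS)])
    table = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=list(AOI_TABLE_COLUMNS))
    )
    table.to_csv(path, index=False)


def read_aoi_table(
    path, geom: ScreenGeometry | None = None, margin_allowance_px: float = 300.0
):
    """Read an AOI CSV back into a list of :class:`AoiTrajectory`.

    Rows violating the box invariant are rejected with their row number.
    Coordinates outside the display (plus ``margin_allowance_px``) trigger a
    warning only, since margin-expanded boxes may legitimately poke past the
    display edge.
    """
    table = pd.read_csv(path)
    for col in AOI_TABLE_COLUMNS[:-1]:
        if col not in table.columns:
            raise ValueError(f"AOI table {path!s} is missing column {col!r}")
    if "label" not in table.columns:
        table["label"] = ""
    table["label"] = table["label"].fillna("")
    bad = (table["x_left"] >= table["x_right"]) | (table["y_top"] >= table["y_bottom"])
    if bad.any():
        rows = (table.index[bad] + 2).tolist()  # 1-based, counting the header
        raise ValueError(f"degenerate AOI box at file row(s) {rows}")
    if geom is not None:
        half_w = geom.width_px / 2 + margin_allowance_px
        half_h = geom.height_px / 2 + margin_allowance_px
        off = (
            (table["x_left"] < -half_w)
            | (table["x_right"] > half_w)
            | (table["y_top"] < -half_h)
            | (table["y_bottom"] > half_h)
        )
        if off.any():
            warnings.warn(f"{int(off.sum())} AOI box(es) far outside the display")
    out = []
    for object_id, group in table.groupby("object_id", sort=True):
        group = group.sort_values("frame")
        out.append(
            AoiTrajectory(
                object_id=str(object_id),
                table=group[["frame", "x_left", "y_top", "x_right", "y_bottom", "label"]],
            )
        )
    return out


@dataclass
class TrackResult:
    """Outcome of semi-automatic tracking."""

    trajectory: AoiTrajectory
    status: str  # "completed" | "lost"
    lost_frame: int | None = None


def _gray(frame: np.ndarray) -> np.ndarray:
    a = np.asarray(frame, dtype=float)
    if a.ndim == 3:
        a = a.mean(axis=2)
    return a


def track_object(
    frames,
    init: AoiBox,
    corrections: dict[int, AoiBox] | None = None,
    *,
    scales=(0.96, 0.98, 1.0, 1.02, 1.04),
    search_pad: int = 24,
    template_pad: int = 6,
    min_corr: float = 0.5,
) -> TrackResult:
    """Track an object from ``init.frame`` to the end of ``frames``.

    The reference tracker is deliberately simple and fully deterministic: the
    previous frame's box content (padded by ``template_pad`` so the object
    edges carry contrast) is matched by normalized cross-correlation against a
    local search window in the next frame, at several relative scales; the best
    (scale, offset) updates the box position and size. A correlation peak below
    ``min_corr`` halts tracking with status ``"lost"``.

    ``corrections`` maps frame index to an override box; an override at a frame
    after a loss resumes tracking there, and the skipped frames are bridged by
    linear box interpolation so the returned trajectory stays contiguous.
    """
    corrections = corrections or {}
    n_frames = len(frames)
    if not 0 <= init.frame < n_frames:
        raise ValueError("init frame outside the video")
    shape = _gray(frames[init.frame]).shape
    half_w, half_h = shape[1] / 2.0, shape[0] / 2.0

    def to_rc(box: AoiBox):
        # centered -> array (row, col) bounds, clipped to the frame
        c0 = int(np.floor(box.x_left + half_w))
        c1 = int(np.ceil(box.x_right + half_w))
        r0 = int(np.floor(box.y_top + half_h))
        r1 = int(np.ceil(box.y_bottom + half_h))
        return max(r0, 0), min(r1, shape[0]), max(c0, 0), min(c1, shape[1])

    boxes: list[AoiBox] = []
    status = "completed"
    lost_frame: int | None = None
    cur = init
    last_tracked: AoiBox | None = None
    lost = False

    for f in range(init.frame, n_frames):
        if f in corrections:
            override = corrections[f]
            if lost and last_tracked is not None:
                # bridge the blind span so the trajectory stays contiguous
                bridge = interpolate_boxes(
                    [
                        AoiBox(
                            last_tracked.frame,
                            last_tracked.x_left,
                            last_tracked.y_top,
                            last_tracked.x_right,
                            last_tracked.y_bottom,
                            init.object_id,
                            init.label,
                        ),
                        AoiBox(
                            f,
                            override.x_left,
                            override.y_top,
                            override.x_right,
                            override.y_bottom,
                            init.object_id,
                            init.label,
                        ),
                    ]
                )
                boxes = boxes[:-1] + [
                    bridge.box_at(k) for k in range(last_tracked.frame, f)
                ]
                lost = False
                status = "completed"
                lost_frame = None
            cur = AoiBox(
                f,
                override.x_left,
                override.y_top,
                override.x_right,
                override.y_bottom,
                init.object_id,
                init.label,
            )
            boxes.append(cur)
            last_tracked = cur
            continue
        if lost:
            continue
        if f == init.frame:
            boxes.append(cur)
            last_tracked = cur
            continue

        prev = _gray(frames[f - 1])
        nxt = _gray(frames[f])
        r0, r1, c0, c1 = to_rc(cur)
        tr0 = max(r0 - template_pad, 0)
        tr1 = min(r1 + template_pad, shape[0])
        tc0 = max(c0 - template_pad, 0)
        tc1 = min(c1 + template_pad, shape[1])
        template = prev[tr0:tr1, tc0:tc1]
        wr0 = max(tr0 - search_pad, 0)
        wr1 = min(tr1 + search_pad, shape[0])
        wc0 = max(tc0 - search_pad, 0)
        wc1 = min(tc1 + search_pad, shape[1])
        window = nxt[wr0:wr1, wc0:wc1]

        # candidate template sizes: +-1 px per axis resolves slow growth of
        # small boxes; relative scales matter once boxes are large
        th0, tw0 = template.shape
        sizes = {(th0 + dh, tw0 + dw) for dh in (-1, 0, 1) for dw in (-1, 0, 1)}
        sizes |= {
            (int(round(th0 * s)), int(round(tw0 * s))) for s in scales
        }
        best = (-np.inf, th0, tw0, 0.0, 0.0)  # corr, th, tw, peak_r, peak_c
        for th, tw in sorted(sizes):
            if th < 3 or tw < 3 or th > window.shape[0] or tw > window.shape[1]:
                continue
            templ = (
                template
                if (th, tw) == template.shape
                else resize(template, (th, tw), anti_aliasing=True)
            )
            if float(templ.std()) == 0.0:
                continue
            corr = match_template(window, templ)
            peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
            val = float(corr[peak])
            if val > best[0]:
                best = (val, th, tw, peak[0] + th / 2.0, peak[1] + tw / 2.0)

        if best[0] < min_corr:
            lost = True
            if status != "lost":
                status = "lost"
                lost_frame = f
            continue

        _, th, tw, pr, pc = best
        cy = wr0 + pr - half_h
        cx = wc0 + pc - half_w
        new_w = cur.width * (tw / tw0)
        new_h = cur.height * (th / th0)
        cur = AoiBox(
            f,
            cx - new_w / 2.0,
            cy - new_h / 2.0,
            cx + new_w / 2.0,
            cy + new_h / 2.0,
            init.object_id,
            init.label,
        )
        boxes.append(cur)
        last_tracked = cur

    rounded = [
        AoiBox(
            b.frame,
            int(np.rint(b.x_left)),
            int(np.rint(b.y_top)),
            int(np.rint(b.x_right)),
            int(np.rint(b.y_bottom)),
            init.object_id,
            init.label,
        )
        for b in boxes
    ]
    return TrackResult(
        trajectory=AoiTrajectory.from_boxes(rounded),
        status=status,
        lost_frame=lost_frame,
    )


def trajectory_summary(
    traj: AoiTrajectory, fps: float = 25.0, geom: ScreenGeometry | None = None
) -> dict:
    """Size and motion summary of a trajectory.

    Widths/heights are reported as median (min-max); the mean velocity is the
    angular distance between the start and end box midpoints divided by the
    visibility duration, negative for right-to-left motion.
    """
    from .geometry import px_to_deg

    geom = geom or ScreenGeometry()
    w = (traj.table["x_right"] - traj.table["x_left"]).to_numpy(dtype=float)
    h = (traj.table["y_bottom"] - traj.table["y_top"]).to_numpy(dtype=float)
    first = traj.box_at(traj.first_frame).center
    last = traj.box_at(traj.last_frame).center
    dx_deg = px_to_deg(last[0], geom) - px_to_deg(first[0], geom)
    dy_deg = px_to_deg(last[1], geom) - px_to_deg(first[1], geom)
    dist_deg = float(np.hypot(dx_deg, dy_deg))
    sign = -1.0 if last[0] < first[0] else 1.0
    duration = traj.duration_s(fps)
    return {
        "object_id": traj.object_id,
        "duration_s": duration,
        "width_median_px": float(np.median(w)),
        "width_min_px": float(w.min()),
        "width_max_px": float(w.max()),
        "height_median_px": float(np.median(h)),
        "height_min_px": float(h.min()),
        "height_max_px": float(h.max()),
        "mean_velocity_deg_s": sign * dist_deg / duration,
    }
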