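"""Overlay AOI boxes and gaze points on stimulus video frames.

Three renderers mirror the analysis outputs: AOI boxes alone (with their
margin-expanded outlines), one participant's gaze over the boxes, and all
participants' gaze at once. Entities are colored from a fixed 26-color
discriminative palette (the "color alphabet" of Green-Armytage), cycling
beyond 26.

Frames are numpy arrays, ``(H, W, 3)`` uint8 RGB (grayscale ``(H, W)`` is
promoted), at the display resolution; a stack is any sequence of frames.
All drawing is pure-numpy and deterministic: identical inputs produce
byte-identical frame buffers. Boxes and gaze arrive in centered display
coordinates and are converted to top-left video coordinates at render time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk

from .annotate import AoiTrajectory
from .geometry import ScreenGeometry
from .match_metrics import MatchParams, frame_of

__all__ = [
    "COLOR_ALPHABET",
    "OverlayStyle",
    "overlay_aois",
    "overlay_single_participant",
    "overlay_multiple_participants",
]

#: Green-Armytage 26-color alphabet (RGB), a palette of maximally
#: discriminative colors for labeling many entities at once.
COLOR_ALPHABET: tuple[tuple[int, int, int], ...] = (
    (240, 163, 255),  # amethyst
    (0, 117, 220),    # blue
    (153, 63, 0),     # caramel
    (76, 0, 92),      # damson
    (25, 25, 25),     # ebony
    (0, 92, 49),      # forest
    (43, 206, 72),    # green
    (255, 204, 153),  # honeydew
    (128, 128, 128),  # iron
    (148, 255, 181),  # jade
    (143, 124, 0),    # khaki
    (157, 204, 0),    # lime
    (194, 0, 136),    # mallow
    (0, 51, 128),     # navy
    (255, 164, 5),    # orpiment
    (255, 168, 187),  # pink
    (66, 102, 0),     # quagmire
    (255, 0, 16),     # red
    (94, 241, 242),   # sky
    (0, 153, 143),    # turquoise
    (224, 255, 102),  # uranium
    (116, 10, 255),   # violet
    (153, 0, 0),      # wine
    (255, 255, 128),  # xanthin
    (255, 225, 0),    # yellow
    (255, 80, 5),     # zinnia
)


@dataclass(frozen=True)
class OverlayStyle:
    """Rendering style shared by all overlay tools."""

    box_thickness: int = 3
    gaze_radius: int = 6
    show_margins: bool = True
    palette: tuple[tuple[int, int, int], ...] = COLOR_ALPHABET

    def color_for(self, index: int) -> tuple[int, int, int]:
        return self.palette[index % len(self.palette)]


def _as_rgb_stack(frames) -> np.ndarray:
    stack = np.asarray(frames)
    if stack.ndim == 3:  # (n, H, W) grayscale
        stack = np.repeat(stack[..., None], 3, axis=3)
    if stack.ndim != 4 or stack.shape[-1] != 3:
        raise ValueError("frames must be (n, H, W) or (n, H, W, 3)")
    return stack.astype(np.uint8, copy=True)


def _draw_rect(img: np.ndarray, r0: float, c0: float, r1: float, c1: float, color, thickness: int) -> None:
    h, w = img.shape[:2]
    r0i, c0i = int(np.floor(r0)), int(np.floor(c0))
    r1i, c1i = int(np.ceil(r1)), int(np.ceil(c1))
    for k in range(thickness):
        rr0, cc0, rr1, cc1 = r0i + k, c0i + k, r1i - k, c1i - k
        if rr0 > rr1 or cc0 > cc1:
            break
        lo_r, hi_r = max(rr0, 0), min(rr1 + 1, h)
        lo_c, hi_c = max(cc0, 0), min(cc1 + 1, w)
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        if 0 <= rr0 < h:
            img[rr0, lo_c:hi_c] = color
        if 0 <= rr1 < h:
            img[rr1, lo_c:hi_c] = color
        if 0 <= cc0 < w:
            img[lo_r:hi_r, cc0] = color
        if 0 <= cc1 < w:
            img[lo_r:hi_r, cc1] = color


def _draw_dot(img: np.ndarray, row: float, col: float, radius: int, color) -> None:
    rr, cc = disk((row, col), radius, shape=img.shape[:2])
    img[rr, cc] = color


def overlay_aois(
    frames,
    trajectories,
    margin_deg: float = 0.0,
    geom: ScreenGeometry | None = None,
    style: OverlayStyle = OverlayStyle(),
) -> np.ndarray:
    """Draw every visible AOI box (and its margin-expanded outline).

    Output preserves frame count, size and dtype; frames without AOIs are
    copied verbatim. AOI frames beyond the video end are skipped with a
    warning.
    """
    from .match_metrics import _expanded_edges

    geom = geom or ScreenGeometry()
    stack = _as_rgb_stack(frames)
    n, h, w = stack.shape[:3]
    half_w, half_h = w / 2.0, h / 2.0
    for i, traj in enumerate(sorted(trajectories, key=lambda tr: tr.object_id)):
        color = style.color_for(i)
        if traj.last_frame >= n:
            warnings.warn(
                f"AOI {traj.object_id!r} extends past the video end; "
                "out-of-range frames skipped"
            )
        exl, exr, eyt, eyb = _expanded_edges(traj, margin_deg, geom)
        for f in range(traj.first_frame, min(traj.last_frame, n - 1) + 1):
            box = traj.box_at(f)
            img = stack[f]
            _draw_rect(
                img,
                box.y_top + half_h,
                box.x_left + half_w,
                box.y_bottom + half_h,
                box.x_right + half_w,
                color,
                style.box_thickness,
            )
            if style.show_margins and margin_deg > 0:
                k = f - traj.first_frame
                _draw_rect(
                    img,
                    eyt[k] + half_h,
                    exl[k] + half_w,
                    eyb[k] + half_h,
                    exr[k] + half_w,
                    color,
                    max(style.box_thickness // 2, 1),
                )
    return stack


def _draw_gaze(
    stack: np.ndarray,
    gaze: pd.DataFrame,
    color,
    style: OverlayStyle,
    fps: float,
) -> None:
    n, h, w = stack.shape[:3]
    t = gaze["t"].to_numpy(dtype=float)
    valid = gaze["valid"].to_numpy(dtype=bool)
    x = gaze["x"].to_numpy(dtype=float)
    y = gaze["y"].to_numpy(dtype=float)
    f = frame_of(t, fps)
    ok = valid & np.isfinite(x) & np.isfinite(y) & (f >= 0) & (f < n)
    for i in np.flatnonzero(ok):
        _draw_dot(stack[f[i]], y[i] + h / 2.0, x[i] + w / 2.0, style.gaze_radius, color)


def overlay_single_participant(
    frames,
    trajectories,
    gaze: pd.DataFrame,
    margin_deg: float = 0.0,
    geom: ScreenGeometry | None = None,
    style: OverlayStyle = OverlayStyle(),
    params: MatchParams = MatchParams(),
    color_index: int = 0,
) -> np.ndarray:
    """AOI boxes plus one participant's gaze dots.

    All gaze samples mapping to a frame are drawn (up to 10 per frame at
    240 Hz); invalid (gap) samples are not drawn — during off-screen
    excursions the dot simply disappears, as it falls outside the display.
    """
    stack = overlay_aois(frames, trajectories, margin_deg, geom, style)
    if len(gaze) == 0:
        warnings.warn("empty gaze stream; rendering AOIs only")
        return stack
    _draw_gaze(stack, gaze, style.color_for(color_index), style, params.fps)
    return stack


def overlay_multiple_participants(
    frames,
    trajectories,
    gaze_streams,
    margin_deg: float = 0.0,
    geom: ScreenGeometry | None = None,
    style: OverlayStyle = OverlayStyle(),
    params: MatchParams = MatchParams(),
) -> np.ndarray:
    """AOI boxes plus the gaze of all participants, one color each.

    ``gaze_streams`` is a mapping participant -> gaze DataFrame; colors are
    assigned in sorted participant order, so the assignment is deterministic.
    """
    stack = overlay_aois(frames, trajectories, margin_deg, geom, style)
    for i, participant in enumerate(sorted(gaze_streams)):
        gaze = gaze_streams[participant]
        if len(gaze) == 0:
            warnings.warn(f"empty gaze stream for participant {participant!r}")
            continue
        _draw_gaze(stack, gaze, style.color_for(i), style, params.fps)
    return stack
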