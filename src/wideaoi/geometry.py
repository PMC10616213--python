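"""Physical model of a flat wide-screen display and visual-angle conversions.

The display is three coplanar LCD panels in a linear formation viewed from a
fixed distance, spanning roughly 100 degrees of horizontal visual angle. Because
the screen is flat, a fixed margin expressed in degrees of visual angle
corresponds to more pixels at the periphery than at the center: the mapping from
centered pixel offset ``x`` to eccentricity is ``theta = atan(x * pitch / d)``,
whose inverse tangent projection stretches toward the edges. All conversions
here use that tangent model.

Coordinates are *centered* screen pixels: (0, 0) at the display center,
+x rightward, +y downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "PixelMargins",
    "px_to_deg",
    "deg_to_px",
    "total_fov_deg",
    "margins_for_box",
    "margins_for_edges",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Pixel and physical model of the three-screen display.

    Parameters
    ----------
    width_px, height_px:
        Stimulus/display resolution in pixels (the full video spans all
        three panels).
    pixel_pitch_cm:
        Physical size of one pixel. The default corresponds to a 24-inch
        16:10 panel, 51.69 cm active width at 1920 px.
    viewing_distance_cm:
        Eye to central screen center, perpendicular distance.
    bezel_px:
        Pixels occluded per screen junction by the bezel-correction of the
        graphics driver. Metadata only: gaze and AOIs share one undivided
        video coordinate space; overlays may draw these bands.
    bezel_cm:
        Physical width of a single panel bezel; each junction contributes two
        bezels to the physical extent of the display.
    n_panels:
        Number of panels in the linear formation.
    """

    width_px: int = 5760
    height_px: int = 1200
    pixel_pitch_cm: float = 0.02692
    viewing_distance_cm: float = 65.0
    bezel_px: int = 50
    bezel_cm: float = 0.68
    n_panels: int = 3

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) <= 0:
            raise ValueError("display resolution must be positive")
        if self.pixel_pitch_cm <= 0 or self.viewing_distance_cm <= 0:
            raise ValueError("pixel pitch and viewing distance must be positive")
        if self.width_px % 2:
            raise ValueError("width_px must be even (centered coordinates)")

    @property
    def junction_positions_px(self) -> tuple[float, ...]:
        """Horizontal junction positions in centered pixels (metadata)."""
        panel = self.width_px / self.n_panels
        half = self.width_px / 2
        return tuple(panel * i - half for i in range(1, self.n_panels))


@dataclass(frozen=True)
class PixelMargins:
    """Per-side pixel expansion of an AOI box for a visual-angle margin."""

    left_px: float
    right_px: float
    top_px: float
    bottom_px: float

    def __post_init__(self) -> None:
        if min(self.left_px, self.right_px, self.top_px, self.bottom_px) < 0:
            raise ValueError("pixel margins must be non-negative")


def px_to_deg(x, geom: ScreenGeometry):
    """Signed eccentricity in degrees for a centered pixel offset.

    Works on scalars or arrays, for either screen axis (same pitch and
    perpendicular viewing distance are assumed in both directions).
    """
    x = np.asarray(x, dtype=float)
    theta = np.degrees(
        np.arctan(x * geom.pixel_pitch_cm / geom.viewing_distance_cm)
    )
    return theta if theta.shape else float(theta)


def deg_to_px(theta, geom: ScreenGeometry):
    """Inverse of :func:`px_to_deg`; raises for angles at or beyond 90 deg."""
    theta = np.asarray(theta, dtype=float)
    if np.any(np.abs(theta) >= 90.0):
        raise ValueError("visual angle must satisfy |theta| < 90 deg")
    x = (
        geom.viewing_distance_cm
        / geom.pixel_pitch_cm
        * np.tan(np.radians(theta))
    )
    return x if x.shape else float(x)


def total_fov_deg(geom: ScreenGeometry) -> float:
    """Total horizontal field of view subtended by the physical display.

    Includes the two panel bezels at each junction (the panels are flush, so
    the physical width is n_panels * active width + 2 bezels per junction).
    """
    active_cm = geom.width_px * geom.pixel_pitch_cm
    bezels_cm = 2 * geom.bezel_cm * (geom.n_panels - 1)
    half_cm = (active_cm + bezels_cm) / 2
    return float(2 * np.degrees(np.arctan(half_cm / geom.viewing_distance_cm)))


def margins_for_edges(
    x_left,
    x_right,
    y_center,
    margin_deg: float,
    geom: ScreenGeometry,
):
    """Vectorized per-side pixel margins for box edges in centered pixels.

    Left and right margins are computed separately at the respective edge
    eccentricities; the vertical margin uses the box-center y eccentricity and
    applies to top and bottom alike. Returns ``(left, right, vertical)``
    arrays (or floats), each clamped at zero.
    """
    if margin_deg < 0:
        raise ValueError("margin_deg must be >= 0")
    if margin_deg == 0:
        zero = np.zeros(np.broadcast(x_left, x_right, y_center).shape)
        if zero.ndim == 0:
            return 0.0, 0.0, 0.0
        return zero, zero.copy(), zero.copy()
    right = deg_to_px(px_to_deg(x_right, geom) + margin_deg, geom) - np.asarray(
        x_right, dtype=float
    )
    left = np.asarray(x_left, dtype=float) - deg_to_px(
        px_to_deg(x_left, geom) - margin_deg, geom
    )
    theta_y = np.abs(px_to_deg(y_center, geom))
    vert = deg_to_px(theta_y + margin_deg, geom) - deg_to_px(theta_y, geom)
    left = np.maximum(left, 0.0)
    right = np.maximum(right, 0.0)
    vert = np.maximum(vert, 0.0)
    if np.ndim(left) == 0:
        return float(left), float(right), float(vert)
    return left, right, vert


def margins_for_box(box, margin_deg: float, geom: ScreenGeometry) -> PixelMargins:
    """Eccentricity-dependent pixel margins for one AOI box.

    ``box`` is any object with ``x_left, x_right, y_top, y_bottom`` attributes
    in centered pixels. The expanded box may extend past the display edge;
    off-screen gaze is handled by gap classification, not by clamping here.
    """
    y_center = (box.y_top + box.y_bottom) / 2.0
    left, right, vert = margins_for_edges(
        box.x_left, box.x_right, y_center, margin_deg, geom
    )
    return PixelMargins(left_px=left, right_px=right, top_px=vert, bottom_px=vert)
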