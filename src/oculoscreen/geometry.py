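"""Screen and viewing geometry: pixel <-> visual-angle conversion.

Every velocity and amplitude downstream is expressed either in raw pixels
or in degrees of visual angle.  The conversion assumes square pixels and a
flat screen viewed on-axis: the physical pixel pitch is derived from the
screen diagonal and resolution, and the angle subtended by an on-screen
displacement ``d`` (mm) at viewing distance ``D`` (mm) is
``atan(d / D)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenGeometry", "DEFAULT_GEOMETRY", "px_to_deg", "deg_to_px"]

_MM_PER_INCH = 25.4


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of the display and viewing position.

    Defaults describe a 23.8-inch 1920x1080 monitor viewed at 70 cm with
    the head stabilised by a chin rest.
    """

    width_px: int = 1920
    height_px: int = 1080
    diagonal_mm: float = 23.8 * _MM_PER_INCH
    viewing_distance_mm: float = 700.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "diagonal_mm", "viewing_distance_mm"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {value!r}")

    @property
    def pixel_pitch_mm(self) -> float:
        """Physical size of one (square) pixel in mm."""
        return self.diagonal_mm / math.hypot(self.width_px, self.height_px)

    @property
    def width_mm(self) -> float:
        return self.pixel_pitch_mm * self.width_px

    @property
    def height_mm(self) -> float:
        return self.pixel_pitch_mm * self.height_px

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


DEFAULT_GEOMETRY = ScreenGeometry()


def px_to_deg(dx, dy, geom: ScreenGeometry = DEFAULT_GEOMETRY):
    """Visual angle (degrees) subtended by an on-screen displacement in pixels.

    Accepts scalars or arrays; the displacement magnitude is the Euclidean
    norm of ``(dx, dy)``.  Zero displacement maps to exactly 0 deg and the
    result is monotone increasing in the displacement magnitude.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if not (np.all(np.isfinite(dx)) and np.all(np.isfinite(dy))):
        raise ValueError("px_to_deg requires finite displacements")
    d_mm = np.hypot(dx, dy) * geom.pixel_pitch_mm
    angle = np.degrees(np.arctan(d_mm / geom.viewing_distance_mm))
    return angle if angle.ndim else float(angle)


def deg_to_px(angle_deg, geom: ScreenGeometry = DEFAULT_GEOMETRY):
    """Inverse of :func:`px_to_deg` for a displacement magnitude."""
    angle_deg = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(angle_deg)):
        raise ValueError("deg_to_px requires finite angles")
    d_mm = np.tan(np.radians(angle_deg)) * geom.viewing_distance_mm
    px = d_mm / geom.pixel_pitch_mm
    return px if px.ndim else float(px)
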