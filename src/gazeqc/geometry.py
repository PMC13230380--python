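"""Coordinate transforms between screen pixels, physical millimetres, 3-D gaze
direction vectors, and angular gaze positions.

The model is a fixed eye on the perpendicular through the centre of a flat
screen, at ``viewing_distance_mm`` from it.  Angles follow the Fick convention:
the azimuth rotation (about the vertical axis) is applied first, the elevation
rotation (about the interim horizontal axis) second.  Rightward and upward are
positive.  The straight-ahead direction is the unit vector (0, 0, 1); any
on-screen point therefore has z > 0.

Pixel coordinates use the common display convention: origin at the top-left
corner, +x rightward, +y downward, and are treated as continuous quantities
(no half-pixel offset), since eye trackers report sub-pixel gaze positions.
The physical (mm) frame is centred on the screen with +y upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError

__all__ = [
    "ScreenGeometry",
    "AngularPosition",
    "pixels_to_mm",
    "mm_to_pixels",
    "mm_to_angles",
    "angles_to_direction",
    "direction_to_angles",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical description of a screen and the viewing distance to it.

    Parameters
    ----------
    width_px, height_px
        Screen resolution in pixels.
    width_mm, height_mm
        Physical size of the displayed area in millimetres.
    viewing_distance_mm
        Distance from the eye to the screen centre, along the screen normal.
    """

    width_px: float
    height_px: float
    width_mm: float
    height_mm: float
    viewing_distance_mm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm",
                     "viewing_distance_mm"):
            value = getattr(self, name)
            if not value > 0:
                raise ConfigError(f"ScreenGeometry.{name} must be > 0, got {value!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenGeometry":
        required = {"width_px", "height_px", "width_mm", "height_mm",
                    "viewing_distance_mm"}
        missing = required - d.keys()
        if missing:
            raise ConfigError(f"screen config missing keys: {sorted(missing)}")
        return cls(**{k: float(d[k]) for k in required})

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreenGeometry":
        """Load screen geometry from a TOML, YAML or JSON key-value file."""
        path = Path(path)
        suffix = path.suffix.lower()
        if suffix == ".toml":
            import tomllib

            with open(path, "rb") as f:
                data = tomllib.load(f)
        elif suffix in (".yaml", ".yml"):
            import yaml

            with open(path, "r", encoding="utf-8") as f:
                data = yaml.safe_load(f)
        elif suffix == ".json":
            import json

            with open(path, "r", encoding="utf-8") as f:
                data = json.load(f)
        else:
            raise ConfigError(f"unsupported screen-config format: {path.name}")
        if not isinstance(data, dict):
            raise ConfigError(f"screen config {path} does not hold a key-value table")
        return cls.from_dict(data)


@dataclass(frozen=True)
class AngularPosition:
    """Gaze or target position as Fick azimuth/elevation angles in degrees."""

    azimuth: float
    elevation: float


def pixels_to_mm(x_px, y_px, screen: ScreenGeometry):
    """Map pixel coordinates to centred physical coordinates in millimetres.

    The pixel frame has its origin at the top-left corner with +y downward;
    the physical frame is centred on the screen with +x rightward and +y
    upward.  The map is affine, so off-screen pixels map linearly outside the
    physical bounds.  Accepts scalars or arrays; NaN passes through.
    """
    x_px = np.asarray(x_px, dtype=float)
    y_px = np.asarray(y_px, dtype=float)
    x_mm = (x_px - screen.width_px / 2.0) * (screen.width_mm / screen.width_px)
    y_mm = (screen.height_px / 2.0 - y_px) * (screen.height_mm / screen.height_px)
    return x_mm, y_mm


def mm_to_pixels(x_mm, y_mm, screen: ScreenGeometry):
    """Inverse of :func:`pixels_to_mm`."""
    x_mm = np.asarray(x_mm, dtype=float)
    y_mm = np.asarray(y_mm, dtype=float)
    x_px = x_mm * (screen.width_px / screen.width_mm) + screen.width_px / 2.0
    y_px = screen.height_px / 2.0 - y_mm * (screen.height_px / screen.height_mm)
    return x_px, y_px


def mm_to_angles(x_mm, y_mm, viewing_distance_mm: float):
    """Convert centred physical screen coordinates to Fick angles in degrees.

    azimuth = atan2(x, d); elevation = atan2(y, hypot(x, d)), i.e. the
    azimuth rotation is applied first and the elevation is measured from the
    azimuth-rotated horizontal plane.
    """
    if not viewing_distance_mm > 0:
        raise ConfigError("viewing_distance_mm must be > 0")
    x_mm = np.asarray(x_mm, dtype=float)
    y_mm = np.asarray(y_mm, dtype=float)
    d = float(viewing_distance_mm)
    azimuth = np.degrees(np.arctan2(x_mm, d))
    elevation = np.degrees(np.arctan2(y_mm, np.hypot(x_mm, d)))
    return azimuth, elevation


def angles_to_direction(azimuth, elevation):
    """Convert Fick angles in degrees to unit gaze direction vectors.

    (0 deg, 0 deg) maps to the straight-ahead direction (0, 0, 1);
    (90, 0) to (1, 0, 0); (0, 90) to (0, 1, 0).

    Returns
    -------
    (x, y, z) components, scalars or arrays matching the input shape.
    """
    azi = np.radians(np.asarray(azimuth, dtype=float))
    ele = np.radians(np.asarray(elevation, dtype=float))
    x = np.cos(ele) * np.sin(azi)
    y = np.sin(ele)
    z = np.cos(ele) * np.cos(azi)
    return x, y, z


def direction_to_angles(x, y, z):
    """Convert direction vectors (any nonzero norm) to Fick angles in degrees.

    Raises
    ------
    ValueError
        If any input vector has zero norm.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    norm = np.sqrt(x * x + y * y + z * z)
    if np.any(norm == 0):
        raise ValueError("cannot convert zero-norm vector to angles")
    azimuth = np.degrees(np.arctan2(x, z))
    elevation = np.degrees(np.arctan2(y, np.hypot(x, z)))
    return azimuth, elevation
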