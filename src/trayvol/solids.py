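"""Parametric food-stand-in solids: height profiles, containment, closed-form volumes.

Each solid sits on the tray plane (z = 0, z increasing toward the camera-facing
top) at a centre (x, y) in tray-plane millimetres.  Shapes are chosen to span
the geometry of plated food: a spherical cap (protein mound), a cylinder
(plated rice), a cuboid (bread/pudding), and a conical frustum (moulded side).

All four are height fields over their footprint, so a top-down depth camera
sees their full upper surface — the regime the integration pipeline assumes.
``height(x, y)`` is the upper surface, ``contains(x, y, z)`` exact solid
membership (used by the voxel oracle), ``analytic_volume()`` the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SolidSpec",
    "SphericalCap",
    "Cylinder",
    "Cuboid",
    "Frustum",
    "make_solid",
]


@dataclass(frozen=True)
class SolidSpec:
    """Base class: a solid of known shape placed on the tray plane."""

    cx: float = 0.0
    cy: float = 0.0
    class_label: str = "food"
    color: tuple[int, int, int] = (255, 0, 0)

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Exact membership; default: below the upper surface (height-field solid)."""
        return (z >= 0) & (z <= self.height(x, y)) & (self.height(x, y) > 0)

    def analytic_volume(self) -> float:  # pragma: no cover
        raise NotImplementedError

    def bbox(self) -> tuple[float, float, float, float, float]:  # pragma: no cover
        """(x_min, x_max, y_min, y_max, z_max) axis-aligned bounds."""
        raise NotImplementedError

    def footprint_contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.height(x, y) > 0


@dataclass(frozen=True)
class SphericalCap(SolidSpec):
    """Cap of a sphere of radius ``radius_mm``, cut ``cap_height_mm`` below the top.

    Volume π·h²·(3R − h)/3; footprint radius √(h·(2R − h)) for h ≤ R.
    h up to 2R is accepted (h = 2R is a full sphere), but only caps with
    h ≤ R are height fields renderable by a top-down depth camera — a
    deeper cut overhangs its footprint (``is_height_field``).
    """

    radius_mm: float = 60.0
    cap_height_mm: float = 40.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.cap_height_mm <= 0:
            raise ValueError("cap radius and height must be > 0")
        if self.cap_height_mm > 2 * self.radius_mm:
            raise ValueError("cap_height_mm cannot exceed the sphere diameter 2R")

    @property
    def is_height_field(self) -> bool:
        return self.cap_height_mm <= self.radius_mm

    @property
    def footprint_radius(self) -> float:
        if self.cap_height_mm >= self.radius_mm:
            return float(self.radius_mm)  # cut at or below the equator
        return float(np.sqrt(self.cap_height_mm * (2 * self.radius_mm - self.cap_height_mm)))

    def height(self, x, y):
        r2 = (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2
        zc = self.cap_height_mm - self.radius_mm  # sphere centre height (<= 0)
        h = zc + np.sqrt(np.maximum(self.radius_mm**2 - r2, 0.0))
        return np.maximum(h, 0.0)

    def contains(self, x, y, z):
        r2 = (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2
        zc = self.cap_height_mm - self.radius_mm
        return (np.asarray(z) >= 0) & (r2 + (np.asarray(z) - zc) ** 2 <= self.radius_mm**2)

    def analytic_volume(self) -> float:
        h, R = self.cap_height_mm, self.radius_mm
        return float(np.pi * h**2 * (3 * R - h) / 3)

    def bbox(self):
        rb = self.footprint_radius
        return (self.cx - rb, self.cx + rb, self.cy - rb, self.cy + rb, self.cap_height_mm)


@dataclass(frozen=True)
class Cylinder(SolidSpec):
    """Right circular cylinder, volume π·R²·h."""

    radius_mm: float = 50.0
    height_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise ValueError("cylinder radius and height must be > 0")

    def height(self, x, y):
        r2 = (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2
        return np.where(r2 <= self.radius_mm**2, self.height_mm, 0.0)

    def analytic_volume(self) -> float:
        return float(np.pi * self.radius_mm**2 * self.height_mm)

    def bbox(self):
        r = self.radius_mm
        return (self.cx - r, self.cx + r, self.cy - r, self.cy + r, self.height_mm)


@dataclass(frozen=True)
class Cuboid(SolidSpec):
    """Axis-aligned box a × b × c, volume a·b·c."""

    side_x_mm: float = 50.0
    side_y_mm: float = 40.0
    height_mm: float = 20.0

    def __post_init__(self) -> None:
        if min(self.side_x_mm, self.side_y_mm, self.height_mm) <= 0:
            raise ValueError("cuboid dimensions must be > 0")

    def height(self, x, y):
        inx = np.abs(np.asarray(x) - self.cx) <= self.side_x_mm / 2
        iny = np.abs(np.asarray(y) - self.cy) <= self.side_y_mm / 2
        return np.where(inx & iny, self.height_mm, 0.0)

    def analytic_volume(self) -> float:
        return float(self.side_x_mm * self.side_y_mm * self.height_mm)

    def bbox(self):
        return (
            self.cx - self.side_x_mm / 2,
            self.cx + self.side_x_mm / 2,
            self.cy - self.side_y_mm / 2,
            self.cy + self.side_y_mm / 2,
            self.height_mm,
        )


@dataclass(frozen=True)
class Frustum(SolidSpec):
    """Conical frustum: base radius R, top radius r <= R, height h.

    Volume π·h·(R² + R·r + r²)/3.
    """

    base_radius_mm: float = 50.0
    top_radius_mm: float = 30.0
    height_mm: float = 35.0

    def __post_init__(self) -> None:
        if min(self.base_radius_mm, self.top_radius_mm, self.height_mm) <= 0:
            raise ValueError("frustum dimensions must be > 0")
        if self.top_radius_mm > self.base_radius_mm:
            raise ValueError("top_radius_mm must be <= base_radius_mm (no overhang)")

    def height(self, x, y):
        rho = np.sqrt((np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2)
        R, r, h = self.base_radius_mm, self.top_radius_mm, self.height_mm
        if R == r:
            return np.where(rho <= R, h, 0.0)
        slope = h / (R - r)
        z = np.where(rho <= r, h, (R - rho) * slope)
        return np.clip(np.where(rho <= R, z, 0.0), 0.0, h)

    def analytic_volume(self) -> float:
        R, r, h = self.base_radius_mm, self.top_radius_mm, self.height_mm
        return float(np.pi * h * (R**2 + R * r + r**2) / 3)

    def bbox(self):
        R = self.base_radius_mm
        return (self.cx - R, self.cx + R, self.cy - R, self.cy + R, self.height_mm)


_SHAPES = {
    "spherical_cap": SphericalCap,
    "cylinder": Cylinder,
    "cuboid": Cuboid,
    "frustum": Frustum,
}


def make_solid(shape: str, **kwargs) -> SolidSpec:
    """Factory by shape name: spherical_cap | cylinder | cuboid | frustum."""
    try:
        cls = _SHAPES[shape]
    except KeyError:
        raise ValueError(f"unknown shape {shape!r}; known: {sorted(_SHAPES)}") from None
    return cls(**kwargs)
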