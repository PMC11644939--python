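"""Pixel-to-millimeter calibration, reference-point depth, and flat-surface check.

Under a pinhole model viewing a plane at distance ``Z``, one pixel spans
``kpix = Z / f`` millimetres on that plane (ground-sampling distance), so
``kpix²`` converts a pixel count to mm² of tray-plane area.  The reference
point is a fixed tray-plane pixel whose (median-windowed) depth defines the
zero-height plane for volume integration.  Before a capture session, a frame
of a bare flat surface is checked for residual structure to confirm the
camera configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rgbd import CameraModel, DepthFrame

__all__ = [
    "PixelScale",
    "ReferencePoint",
    "FlatnessReport",
    "compute_kpix",
    "pick_reference_depth",
    "check_flat_surface",
]


@dataclass(frozen=True)
class PixelScale:
    """mm spanned by one pixel on a plane at ``reference_depth_mm``."""

    kpix: float
    reference_depth_mm: float

    def __post_init__(self) -> None:
        if self.kpix <= 0:
            raise ValueError(f"kpix must be > 0, got {self.kpix}")
        if self.reference_depth_mm <= 0:
            raise ValueError(f"reference depth must be > 0, got {self.reference_depth_mm}")


@dataclass(frozen=True)
class ReferencePoint:
    """Fixed tray-plane pixel (0-based column u, row v) and its depth RP in mm."""

    u: int
    v: int
    depth_mm: float


@dataclass(frozen=True)
class FlatnessReport:
    mean_depth_mm: float
    std_depth_mm: float
    max_abs_residual_mm: float
    passed: bool


def compute_kpix(cam: CameraModel, distance_mm: float) -> PixelScale:
    """Ground-sampling distance at ``distance_mm``: kpix = Z / f."""
    if distance_mm <= 0:
        raise ValueError(f"distance must be > 0 mm, got {distance_mm}")
    return PixelScale(kpix=distance_mm / cam.focal_length_px, reference_depth_mm=distance_mm)


def pick_reference_depth(depth: DepthFrame, u: int, v: int, window: int = 2) -> ReferencePoint:
    """Median of valid depths in the (2·window+1)² neighbourhood of (u, v).

    The point is chosen once per installation (a bare tray-plane pixel) and
    held constant across a session; the median window makes it robust to
    speckle at the chosen pixel.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    h, w = depth.shape
    if not (0 <= u < w and 0 <= v < h):
        raise ValueError(f"reference point ({u}, {v}) outside frame {w}x{h}")
    r0, r1 = max(0, v - window), min(h, v + window + 1)
    c0, c1 = max(0, u - window), min(w, u + window + 1)
    patch = depth.values[r0:r1, c0:c1]
    ok = depth.valid[r0:r1, c0:c1]
    if not ok.any():
        raise ValueError(
            f"no valid depth in the {2 * window + 1}x{2 * window + 1} window at ({u}, {v}); "
            "reference unavailable"
        )
    return ReferencePoint(u=u, v=v, depth_mm=float(np.median(patch[ok])))


def check_flat_surface(depth: DepthFrame, tolerance_mm: float) -> FlatnessReport:
    """Sanity check on a capture of a bare flat surface.

    Reports mean, std and the worst absolute residual |depth − mean| over the
    valid pixels; passes iff the worst residual is within ``tolerance_mm``.
    No plane is fitted — the surface is assumed fronto-parallel, as in the
    fixed overhead mount.
    """
    vals = depth.values[depth.valid]
    if vals.size < 0.5 * depth.values.size:
        raise ValueError(
            f"only {vals.size}/{depth.values.size} pixels valid (<50%); capture unusable"
        )
    mean = float(vals.mean())
    resid = np.abs(vals - mean)
    max_resid = float(resid.max())
    return FlatnessReport(
        mean_depth_mm=mean,
        std_depth_mm=float(vals.std()),
        max_abs_residual_mm=max_resid,
        passed=bool(max_resid <= tolerance_mm),
    )
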