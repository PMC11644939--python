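"""Mask-gated volume integration over a depth map.

Food volume is measured as a height field relative to the tray plane.  With a
fixed reference depth RP (the tray at the reference point) and a saturated
depth map, each masked pixel contributes a column of height

    sup(s, k) = in(s, k) · (RP − depth_sat(s, k))    [mm]

and cross-section kpix² mm², so the class volume is V = Σ sup · kpix² in mm³.
Pixels below the reference plane (concave plate interiors, sensor noise)
would contribute negative columns; they are clamped to zero and counted, as
are masked pixels with no valid depth — both counts let callers reject frames
with excessive dropout instead of silently absorbing it.

A voxel-counting oracle over the parametric solids provides an independent
volume estimate for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import PixelScale, ReferencePoint
from .rgbd import DepthFrame, saturate_depth
from .segmentation import SegmentationMask
from .solids import SolidSpec

__all__ = [
    "SurfaceMap",
    "VolumeResult",
    "HeightMesh",
    "surface_contribution",
    "integrate_volume",
    "compute_dish_volumes",
    "build_mesh",
    "voxel_volume_oracle",
]


@dataclass
class SurfaceMap:
    """Per-pixel height above the reference plane, zero outside the mask."""

    sup: np.ndarray
    pixel_scale: PixelScale
    reference: ReferencePoint
    class_label: str
    pixel_count: int
    clamped_negative_count: int
    invalid_in_mask_count: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.sup.shape


@dataclass(frozen=True)
class VolumeResult:
    class_label: str
    volume_mm3: float
    pixel_count: int
    clamped_negative_count: int
    invalid_in_mask_count: int

    def as_dict(self) -> dict:
        return {
            "class": self.class_label,
            "volume_mm3": self.volume_mm3,
            "pixel_count": self.pixel_count,
            "clamped_negative_count": self.clamped_negative_count,
            "invalid_in_mask_count": self.invalid_in_mask_count,
        }


@dataclass
class HeightMesh:
    """Regular-grid triangulation of a surface map, axes in mm.

    ``vertices`` has one row per grid point (x, y, z) with x, y spaced by
    kpix and z equal to sup; ``faces`` are triangle vertex indices.
    ``orientation`` records the intended view for visualization.
    """

    vertices: np.ndarray
    faces: np.ndarray
    orientation: str = "top_view"

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def export(self, path: str | Path) -> None:
        """Write the mesh; format from suffix (.ply binary little-endian, .obj)."""
        path = Path(path)
        mesh = self.to_trimesh()
        if path.suffix.lower() == ".ply":
            path.write_bytes(mesh.export(file_type="ply", encoding="binary"))
        elif path.suffix.lower() == ".obj":
            path.write_text(mesh.export(file_type="obj"))
        else:
            raise ValueError(f"unsupported mesh format {path.suffix!r}; use .ply or .obj")


def surface_contribution(
    depth_sat: DepthFrame, mask: SegmentationMask, ref: ReferencePoint, scale: PixelScale
) -> SurfaceMap:
    """Compute sup(s,k) = in(s,k) · (RP − depth_sat(s,k)), clamped at zero.

    ``depth_sat`` must already be saturated.  Masked pixels with invalid depth
    contribute zero and are tallied in ``invalid_in_mask_count``; below-plane
    pixels are clamped to zero and tallied in ``clamped_negative_count``.
    """
    if depth_sat.shape != mask.shape:
        raise ValueError(
            f"depth shape {depth_sat.shape} does not match mask shape {mask.shape}"
        )
    in_mask = mask.mask
    usable = in_mask & depth_sat.valid
    raw = np.where(usable, ref.depth_mm - depth_sat.values, 0.0)
    negative = usable & (raw < 0)
    sup = np.where(negative, 0.0, raw)
    return SurfaceMap(
        sup=sup,
        pixel_scale=scale,
        reference=ref,
        class_label=mask.class_label,
        pixel_count=int(in_mask.sum()),
        clamped_negative_count=int(negative.sum()),
        invalid_in_mask_count=int((in_mask & ~depth_sat.valid).sum()),
    )


def integrate_volume(sup: SurfaceMap) -> VolumeResult:
    """V = Σ sup(s,k) · kpix²  [mm³]."""
    if not np.all(np.isfinite(sup.sup)):
        raise ValueError("surface map contains non-finite values")
    volume = float(sup.sup.sum(dtype=np.float64) * sup.pixel_scale.kpix**2)
    return VolumeResult(
        class_label=sup.class_label,
        volume_mm3=volume,
        pixel_count=sup.pixel_count,
        clamped_negative_count=sup.clamped_negative_count,
        invalid_in_mask_count=sup.invalid_in_mask_count,
    )


def compute_dish_volumes(
    depth: DepthFrame,
    masks: Sequence[SegmentationMask],
    ref: ReferencePoint,
    scale: PixelScale,
    sat_min: float,
    sat_max: float,
) -> list[VolumeResult]:
    """Full per-frame volume stage: saturate, then integrate each class mask."""
    depth_sat = saturate_depth(depth, sat_min, sat_max)
    out = []
    for mask in masks:
        sup = surface_contribution(depth_sat, mask, ref, scale)
        out.append(integrate_volume(sup))
    return out


def build_mesh(sup: SurfaceMap) -> HeightMesh:
    """Triangulate the surface map on its pixel grid, axes scaled to mm."""
    if not np.all(np.isfinite(sup.sup)):
        raise ValueError("surface map contains non-finite values")
    h, w = sup.shape
    k = sup.pixel_scale.kpix
    xs = np.arange(w) * k
    ys = np.arange(h) * k
    xx, yy = np.meshgrid(xs, ys)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), sup.sup.ravel()])
    idx = np.arange(h * w).reshape(h, w)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([b, d, c])], axis=0
    )
    return HeightMesh(vertices=vertices, faces=faces, orientation="top_view")


def voxel_volume_oracle(solid: SolidSpec, voxel_mm: float) -> float:
    """Brute-force volume: count voxel centres inside the solid × voxel³.

    Independent of the height-field integration path; converges to the
    analytic volume as the voxel size shrinks.  Evaluated slab-by-slab in z
    to bound memory.
    """
    if voxel_mm <= 0:
        raise ValueError(f"voxel_mm must be > 0, got {voxel_mm}")
    x0, x1, y0, y1, zmax = solid.bbox()
    # half-voxel margin so boundary voxel centres are all covered
    xs = np.arange(x0 + voxel_mm / 2, x1, voxel_mm)
    ys = np.arange(y0 + voxel_mm / 2, y1, voxel_mm)
    zs = np.arange(voxel_mm / 2, zmax, voxel_mm)
    if not (xs.size and ys.size and zs.size):
        return 0.0
    xx, yy = np.meshgrid(xs, ys)
    count = 0
    for z in zs:
        count += int(solid.contains(xx, yy, np.full_like(xx, z)).sum())
    return float(count) * voxel_mm**3
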