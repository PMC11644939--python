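"""Synthetic top-down tray scenes with known ground truth.

The renderer emulates an overhead RGB-D rig looking straight down at a flat
tray: the pixel grid samples the tray plane orthographically with spacing
kpix = tray_depth / focal_length (the ground-sampling distance at the tray),
and each pixel's depth is tray_depth minus the local scene height.  Food
solids have closed-form volumes, exact masks, and flat palette colours, so
every stage of the measurement pipeline can be checked against ground truth.

Sensor imperfections are modelled in the disparity domain, where a stereo
matcher actually works: depths are converted to disparity, rounded to the
matcher's subpixel quantization step, perturbed by Gaussian matching noise,
and converted back — which reproduces the quadratic growth of depth error
with distance.  Low-texture failure is modelled as dropout regions that
either invalidate pixels or flatten them to a fixed height (the
"flattened top" failure mode seen on smooth proteins).

The module also synthesizes volume–weight training sets under a known law
(linear, as observed for rice; smooth nonlinear, as observed for chicken)
for exercising the regression stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .rgbd import CameraModel, DepthFrame, depth_to_disparity, disparity_to_depth, DisparityFrame
from .segmentation import SegmentationMask
from .solids import SolidSpec, make_solid
from .weight import VolumeWeightSet

__all__ = [
    "PlateSpec",
    "DropoutRegion",
    "NoiseSpec",
    "SceneSpec",
    "RenderBundle",
    "render_scene",
    "apply_stereo_noise",
    "LinearLaw",
    "PowerLaw",
    "generate_weight_dataset",
    "chicken_like_dataset",
    "rice_like_dataset",
    "default_camera",
    "default_scene",
]


def default_camera() -> CameraModel:
    """Overhead rig used throughout: kpix = 1200/2400 = 0.5 mm/px at the tray."""
    return CameraModel(
        focal_length_px=2400.0,
        baseline_mm=75.0,
        width_px=640,
        height_px=480,
        mount_height_mm=1200.0,
    )


@dataclass(frozen=True)
class PlateSpec:
    """A plate rendered as a flat disc with a raised rim annulus."""

    cx: float
    cy: float
    radius_mm: float
    rim_height_mm: float = 10.0
    rim_width_mm: float = 8.0
    color: tuple[int, int, int] = (240, 240, 240)

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        rho = np.sqrt((x - self.cx) ** 2 + (y - self.cy) ** 2)
        rim = (rho <= self.radius_mm) & (rho >= self.radius_mm - self.rim_width_mm)
        return np.where(rim, self.rim_height_mm, 0.0)

    def footprint_contains(self, x, y):
        rho2 = (x - self.cx) ** 2 + (y - self.cy) ** 2
        return rho2 <= self.radius_mm**2


@dataclass(frozen=True)
class DropoutRegion:
    """Where and how stereo matching fails.

    ``region`` selects pixels: either a half-open pixel bbox
    (u_min, v_min, u_max, v_max) or a class label, which selects that class's
    ground-truth mask.  ``mode`` is "invalid" (no depth) or "flatten", which
    caps the scene height at ``flatten_to_mm`` — the matcher latching onto the
    surrounding texture instead of the featureless top.
    """

    region: tuple[int, int, int, int] | str
    mode: str = "flatten"
    flatten_to_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("invalid", "flatten"):
            raise ValueError(f"mode must be 'invalid' or 'flatten', got {self.mode!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Stereo capture noise: subpixel quantization step, matching noise, dropout."""

    disparity_quantization_px: float = 0.125
    gaussian_depth_sigma_mm: float = 0.0
    dropout_regions: tuple[DropoutRegion, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disparity_quantization_px < 0:
            raise ValueError("disparity quantization must be >= 0")
        if self.gaussian_depth_sigma_mm < 0:
            raise ValueError("depth noise sigma must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    camera: CameraModel = field(default_factory=default_camera)
    tray_depth_mm: float = 1200.0
    solids: tuple[SolidSpec, ...] = ()
    plate: Optional[PlateSpec] = None
    noise: Optional[NoiseSpec] = None
    background_color: tuple[int, int, int] = (90, 90, 90)

    def __post_init__(self) -> None:
        if not (0.2 * self.camera.mount_height_mm <= self.tray_depth_mm <= 5 * self.camera.mount_height_mm):
            raise ValueError(
                f"tray depth {self.tray_depth_mm} mm implausible for a camera mounted "
                f"at {self.camera.mount_height_mm} mm"
            )

    @property
    def kpix(self) -> float:
        return self.tray_depth_mm / self.camera.focal_length_px


@dataclass
class RenderBundle:
    depth: DepthFrame
    rgb: np.ndarray
    confidence: np.ndarray
    masks: list[SegmentationMask]
    analytic_volumes_mm3: dict[str, float]
    scene: SceneSpec

    @property
    def palette(self) -> dict[str, tuple[int, int, int]]:
        return {s.class_label: s.color for s in self.scene.solids}


def _tray_plane_coords(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Tray-plane (x, y) mm of every pixel centre, origin at the frame centre."""
    cam = spec.camera
    k = spec.kpix
    xs = (np.arange(cam.width_px) + 0.5 - cam.width_px / 2) * k
    ys = (np.arange(cam.height_px) + 0.5 - cam.height_px / 2) * k
    return np.meshgrid(xs, ys)


def render_scene(spec: SceneSpec) -> RenderBundle:
    """Render a scene spec into a depth/RGB/mask/ground-truth bundle.

    Solids must have pairwise-disjoint footprints and lie fully inside the
    frame.  If the spec carries a noise model it is applied after the clean
    render (see :func:`apply_stereo_noise`).
    """
    cam = spec.camera
    x, y = _tray_plane_coords(spec)
    half_w = cam.width_px * spec.kpix / 2
    half_h = cam.height_px * spec.kpix / 2
    height = np.zeros(cam.shape)
    rgb = np.empty(cam.shape + (3,), dtype=np.uint8)
    rgb[:] = spec.background_color
    if spec.plate is not None:
        height = np.maximum(height, spec.plate.height(x, y))
        rgb[spec.plate.footprint_contains(x, y)] = spec.plate.color
    masks: list[SegmentationMask] = []
    volumes: dict[str, float] = {}
    claimed = np.zeros(cam.shape, dtype=bool)
    for solid in spec.solids:
        if not getattr(solid, "is_height_field", True):
            raise ValueError(
                f"solid {solid.class_label!r} is not a height field (it overhangs "
                "its footprint); a top-down depth render would overestimate it"
            )
        x0, x1, y0, y1, _ = solid.bbox()
        if x0 < -half_w or x1 > half_w or y0 < -half_h or y1 > half_h:
            raise ValueError(
                f"solid {solid.class_label!r} footprint {x0, x1, y0, y1} exceeds the "
                f"frame extent ±({half_w}, {half_h}) mm"
            )
        fp = solid.footprint_contains(x, y)
        if np.any(fp & claimed):
            raise ValueError(f"solid {solid.class_label!r} overlaps another solid's footprint")
        claimed |= fp
        height = np.where(fp, solid.height(x, y), height)
        rgb[fp] = solid.color
        masks.append(SegmentationMask(class_label=solid.class_label, mask=fp))
        volumes[solid.class_label] = solid.analytic_volume()
    depth = DepthFrame(spec.tray_depth_mm - height)
    confidence = np.full(cam.shape, 255, dtype=np.uint8)
    bundle = RenderBundle(
        depth=depth,
        rgb=rgb,
        confidence=confidence,
        masks=masks,
        analytic_volumes_mm3=volumes,
        scene=spec,
    )
    if spec.noise is not None:
        bundle = apply_stereo_noise(bundle, spec.noise)
    return bundle


def _region_mask(bundle: RenderBundle, region) -> np.ndarray:
    if isinstance(region, str):
        for m in bundle.masks:
            if m.class_label == region:
                return m.mask
        raise ValueError(f"dropout region references unknown class {region!r}")
    u0, v0, u1, v1 = region
    sel = np.zeros(bundle.depth.shape, dtype=bool)
    sel[v0:v1, u0:u1] = True
    return sel


def apply_stereo_noise(bundle: RenderBundle, noise: NoiseSpec) -> RenderBundle:
    """Apply disparity-domain quantization/noise and dropout to a clean bundle.

    Deterministic under ``noise.seed``; a zero noise spec returns an
    identical-depth bundle.
    """
    cam = bundle.scene.camera
    depth = bundle.depth
    values = depth.values.copy()
    valid = depth.valid.copy()

    # flatten-mode dropout acts on scene height before the disparity model,
    # as the matcher reports the surrounding surface instead of the true top
    tray = bundle.scene.tray_depth_mm
    for region in noise.dropout_regions:
        sel = _region_mask(bundle, region.region)
        if region.mode == "flatten":
            floor_depth = tray - region.flatten_to_mm
            values[sel] = np.maximum(values[sel], floor_depth)

    disp = depth_to_disparity(DepthFrame(values, valid), cam)
    d = disp.values.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.gaussian_depth_sigma_mm > 0:
        # depth sigma at the tray, expressed in disparity: σ_d = f·B·σ_z / Z²
        sigma_d = (
            cam.focal_length_px
            * cam.baseline_mm
            * noise.gaussian_depth_sigma_mm
            / tray**2
        )
        d = np.where(valid, d + rng.normal(0.0, sigma_d, size=d.shape), d)
    if noise.disparity_quantization_px > 0:
        q = noise.disparity_quantization_px
        d = np.where(valid, np.round(d / q) * q, d)
    d = np.maximum(d, 0.0)
    noisy = disparity_to_depth(DisparityFrame(d), cam)
    values, valid = noisy.values, noisy.valid

    confidence = bundle.confidence.copy()
    for region in noise.dropout_regions:
        if region.mode == "invalid":
            sel = _region_mask(bundle, region.region)
            valid = valid & ~sel
            values = np.where(valid, values, 0.0)
            confidence[sel] = 0
    return RenderBundle(
        depth=DepthFrame(values, valid),
        rgb=bundle.rgb.copy(),
        confidence=confidence,
        masks=[SegmentationMask(m.class_label, m.mask.copy()) for m in bundle.masks],
        analytic_volumes_mm3=dict(bundle.analytic_volumes_mm3),
        scene=replace(bundle.scene, noise=noise),
    )


def default_scene(noise: Optional[NoiseSpec] = None) -> SceneSpec:
    """A plated tray: protein mound, rice cylinder, and a moulded side on a plate."""
    return SceneSpec(
        solids=(
            make_solid(
                "spherical_cap", cx=-60, cy=0, radius_mm=60, cap_height_mm=40,
                class_label="chicken", color=(180, 110, 40),
            ),
            make_solid(
                "cylinder", cx=70, cy=-45, radius_mm=42, height_mm=28,
                class_label="rice", color=(250, 245, 210),
            ),
            make_solid(
                "frustum", cx=70, cy=60, base_radius_mm=35, top_radius_mm=22,
                height_mm=30, class_label="fries", color=(235, 180, 60),
            ),
        ),
        plate=None,
        noise=noise,
    )


# -- volume–weight data synthesis ----------------------------------------


@dataclass(frozen=True)
class LinearLaw:
    """weight = slope·V + intercept; slope defaults to a rice-like 9e-4 g/mm³."""

    slope_g_per_mm3: float = 9e-4
    intercept_g: float = 0.0

    def __call__(self, volume_mm3):
        return self.slope_g_per_mm3 * np.asarray(volume_mm3) + self.intercept_g


@dataclass(frozen=True)
class PowerLaw:
    """Smooth concave law weight = coeff·V^exponent.

    With coeff 0.5 and exponent 0.5 this gives ~250 g at 250,000 mm³ — a
    chicken-like effective density of ~0.001 g/mm³ with density decreasing in
    portion size (bone/void fraction grows with the piece).
    """

    coeff: float = 0.5
    exponent: float = 0.5

    def __call__(self, volume_mm3):
        return self.coeff * np.asarray(volume_mm3, dtype=float) ** self.exponent


def generate_weight_dataset(
    n: int,
    law: Callable[[np.ndarray], np.ndarray],
    noise_sigma_g: float = 0.0,
    relative_noise: float = 0.0,
    volume_range_mm3: tuple[float, float] = (1e5, 4e5),
    seed: int = 0,
    class_label: str = "food",
) -> VolumeWeightSet:
    """Draw volumes uniformly and apply ``law`` with additive and/or multiplicative noise.

    weights = law(V)·(1 + ε_rel) + ε_abs with ε_rel ~ N(0, relative_noise) and
    ε_abs ~ N(0, noise_sigma_g).  Reproducible under ``seed``; the generating
    law is available to tests through the returned set's ``.law`` attribute.
    """
    if n < 4:
        raise ValueError("need n >= 4 records")
    rng = np.random.default_rng(seed)
    volumes = rng.uniform(*volume_range_mm3, size=n)
    weights = np.asarray(law(volumes), dtype=float)
    if relative_noise > 0:
        weights = weights * (1.0 + rng.normal(0.0, relative_noise, size=n))
    if noise_sigma_g > 0:
        weights = weights + rng.normal(0.0, noise_sigma_g, size=n)
    weights = np.maximum(weights, 1e-6)
    out = VolumeWeightSet(
        volumes_mm3=volumes,
        weights_g=weights,
        class_labels=[class_label] * n,
    )
    out.law = law  # type: ignore[attr-defined]
    return out


def chicken_like_dataset(n: int = 72, seed: int = 0) -> VolumeWeightSet:
    """Smooth-nonlinear regime: concave power law with 2% multiplicative noise."""
    return generate_weight_dataset(
        n, PowerLaw(), relative_noise=0.02, seed=seed, class_label="chicken"
    )


def rice_like_dataset(n: int = 48, seed: int = 0) -> VolumeWeightSet:
    """Linear regime: rice-like density line with additive 10 g scale noise."""
    return generate_weight_dataset(
        n,
        LinearLaw(),
        noise_sigma_g=10.0,
        volume_range_mm3=(1e5, 3.5e5),
        seed=seed,
        class_label="rice",
    )
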