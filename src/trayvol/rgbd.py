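"""Stereo camera model, depth/disparity frames, and the depth post-processing chain.

A stereo pair with focal length ``f`` (pixels) and baseline ``B`` (mm) sees a
point at depth ``Z`` (mm) at a disparity of ``d = f·B/Z`` pixels; inverting
gives ``Z = f·B/d``.  Disparity 0 is the sentinel for "no stereo match"; at the
depth level validity is an explicit boolean grid so that missing measurements
can never leak as zeros into downstream sums.

The post-processing chain mirrors a typical stereo depth camera configuration:
confidence gating on the matcher's per-pixel confidence, a median filter
against speckle, an exponential temporal filter for frame-to-frame stability,
an edge-aware spatial smoother, temporal decimation of the frame stream, and
finally saturation of depths to a plausible working band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CameraModel",
    "DisparityFrame",
    "DepthFrame",
    "FilterConfig",
    "disparity_to_depth",
    "depth_to_disparity",
    "apply_confidence_gate",
    "apply_median_filter",
    "apply_temporal_filter",
    "apply_spatial_filter",
    "decimate_stream",
    "saturate_depth",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole/stereo intrinsics.

    Parameters
    ----------
    focal_length_px:
        Focal length in pixels (physical focal length times pixels-per-mm).
    baseline_mm:
        Physical distance between the two stereo sensors, in mm.
    width_px, height_px:
        Sensor resolution.
    mount_height_mm:
        Nominal camera-to-tray distance; the rig hangs ~1.2 m above the tray.
    """

    focal_length_px: float
    baseline_mm: float
    width_px: int
    height_px: int
    mount_height_mm: float = 1200.0

    def __post_init__(self) -> None:
        if self.focal_length_px <= 0:
            raise ValueError(f"focal_length_px must be > 0, got {self.focal_length_px}")
        if self.baseline_mm <= 0:
            raise ValueError(f"baseline_mm must be > 0, got {self.baseline_mm}")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError(
                f"frame dimensions must be >= 1, got {self.width_px}x{self.height_px}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) array shape of frames from this camera."""
        return (self.height_px, self.width_px)


@dataclass
class DisparityFrame:
    """Stereo disparity in pixels; 0 encodes "no stereo match".

    ``confidence`` is the matcher's optional per-pixel confidence in 0–255.
    """

    values: np.ndarray
    confidence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"disparity grid must be 2-D, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("disparity values must be >= 0 (0 = no match)")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence)
            if self.confidence.shape != self.values.shape:
                raise ValueError(
                    f"confidence shape {self.confidence.shape} does not match "
                    f"disparity shape {self.values.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DepthFrame:
    """Depth map in mm with an explicit validity grid.

    Invalid pixels carry the value 0 but are only ever interpreted through
    ``valid``; no operation in this package reads an invalid pixel's value.
    """

    values: np.ndarray
    valid: Optional[np.ndarray] = None
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"depth grid must be 2-D, got shape {self.values.shape}")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError(
                    f"validity shape {self.valid.shape} does not match "
                    f"depth shape {self.values.shape}"
                )
        vals = self.values[self.valid]
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("valid depths must be finite and >= 0 mm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "DepthFrame":
        return DepthFrame(self.values.copy(), self.valid.copy(), self.timestamp)


@dataclass(frozen=True)
class FilterConfig:
    """Depth post-processing configuration (camera-style parameter surface).

    Defaults follow the deployed capture configuration: 7x7 median, temporal
    alpha 0.1, spatial alpha 0.1 / radius 2 / delta 0 with four iterations,
    confidence threshold 200, temporal decimation factor 2.
    """

    median_kernel: int = 7
    temporal_alpha: float = 0.1
    spatial_alpha: float = 0.1
    spatial_radius: int = 2
    spatial_delta: float = 0.0
    spatial_iterations: int = 4
    confidence_threshold: int = 200
    decimation_factor: int = 2

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError(f"median_kernel must be odd and >= 1, got {self.median_kernel}")
        if not (0 < self.temporal_alpha <= 1):
            raise ValueError(f"temporal_alpha must be in (0, 1], got {self.temporal_alpha}")
        if not (0 < self.spatial_alpha <= 1):
            raise ValueError(f"spatial_alpha must be in (0, 1], got {self.spatial_alpha}")
        if self.spatial_radius < 0:
            raise ValueError("spatial_radius must be >= 0")
        if self.spatial_delta < 0:
            raise ValueError("spatial_delta must be >= 0")
        if self.spatial_iterations < 0:
            raise ValueError("spatial_iterations must be >= 0")
        if not (0 <= self.confidence_threshold <= 255):
            raise ValueError("confidence_threshold must be in 0..255")
        if self.decimation_factor < 1:
            raise ValueError(f"decimation_factor must be >= 1, got {self.decimation_factor}")


def _check_frame_matches_camera(shape: tuple[int, int], cam: CameraModel) -> None:
    if shape != cam.shape:
        raise ValueError(
            f"frame shape {shape} does not match camera frame shape {cam.shape}"
        )


def disparity_to_depth(disp: DisparityFrame, cam: CameraModel) -> DepthFrame:
    """Convert stereo disparity (px) to depth (mm): Z = f·B/d.

    Pixels with disparity 0 (no stereo match) are marked invalid rather than
    mapped to infinity.
    """
    _check_frame_matches_camera(disp.shape, cam)
    valid = disp.values > 0
    depth = np.zeros_like(disp.values)
    np.divide(cam.focal_length_px * cam.baseline_mm, disp.values, out=depth, where=valid)
    return DepthFrame(depth, valid)


def depth_to_disparity(depth: DepthFrame, cam: CameraModel) -> DisparityFrame:
    """Inverse conversion d = f·B/Z; invalid pixels map to disparity 0.

    Needed by the scene simulator's disparity-domain quantization model.
    """
    _check_frame_matches_camera(depth.shape, cam)
    if np.any(depth.values[depth.valid] <= 0):
        raise ValueError("cannot convert nonpositive valid depth to disparity")
    disp = np.zeros_like(depth.values)
    np.divide(
        cam.focal_length_px * cam.baseline_mm, depth.values, out=disp, where=depth.valid
    )
    return DisparityFrame(disp)


def apply_confidence_gate(disp: DisparityFrame, threshold: int) -> DisparityFrame:
    """Invalidate (set to disparity 0) pixels whose matcher confidence is below threshold."""
    if disp.confidence is None:
        raise ValueError("disparity frame has no confidence grid; gate cannot be applied")
    if not (0 <= threshold <= 255):
        raise ValueError(f"confidence threshold must be in 0..255, got {threshold}")
    out = disp.values.copy()
    out[disp.confidence < threshold] = 0.0
    return DisparityFrame(out, disp.confidence.copy())


def apply_median_filter(depth: DepthFrame, kernel: int) -> DepthFrame:
    """Validity-aware median filter.

    Each valid pixel is replaced by the median of the *valid* depths in its
    kernel×kernel window; invalid pixels are excluded from the window
    statistic and stay invalid.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return depth.copy()
    r = kernel // 2
    padded = np.pad(
        np.where(depth.valid, depth.values, np.nan),
        r,
        mode="constant",
        constant_values=np.nan,
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, (kernel, kernel))
    with warnings.catch_warnings():
        # windows centred on invalid pixels may be all-NaN; their result is discarded
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(windows.reshape(depth.shape + (kernel * kernel,)), axis=-1)
    out = np.where(depth.valid, med, 0.0)
    # a valid centre pixel always contributes itself, so med is finite there
    return DepthFrame(out, depth.valid.copy(), depth.timestamp)


def apply_temporal_filter(
    frames: Sequence[DepthFrame], alpha: float
) -> list[DepthFrame]:
    """Per-pixel exponential moving average across a frame sequence.

    out_t = alpha·in_t + (1−alpha)·out_{t−1}, out_0 = in_0.  A pixel invalid
    at time t holds its previous filtered state (the stabilizer does not
    manufacture measurements: a pixel never yet observed stays invalid).
    """
    if not frames:
        raise ValueError("temporal filter needs at least one frame")
    if not (0 < alpha <= 1):
        raise ValueError(f"temporal alpha must be in (0, 1], got {alpha}")
    shape = frames[0].shape
    state = np.zeros(shape)
    state_valid = np.zeros(shape, dtype=bool)
    out: list[DepthFrame] = []
    for f in frames:
        if f.shape != shape:
            raise ValueError(
                f"frame shape drifted across sequence: {f.shape} vs {shape}"
            )
        fresh = f.valid & ~state_valid
        both = f.valid & state_valid
        state = np.where(both, alpha * f.values + (1 - alpha) * state, state)
        state = np.where(fresh, f.values, state)
        state_valid = state_valid | f.valid
        out.append(DepthFrame(np.where(state_valid, state, 0.0), state_valid.copy(), f.timestamp))
    return out


def _spatial_pass(values: np.ndarray, valid: np.ndarray, cfg: FilterConfig, axis: int) -> np.ndarray:
    """One directional pass of the edge-aware truncated-exponential smoother."""
    weights_base = (1.0 - cfg.spatial_alpha) ** np.abs(
        np.arange(-cfg.spatial_radius, cfg.spatial_radius + 1)
    )
    acc = np.zeros_like(values)
    wsum = np.zeros_like(values)
    for off, w in zip(range(-cfg.spatial_radius, cfg.spatial_radius + 1), weights_base):
        shifted = np.roll(values, off, axis=axis)
        shifted_valid = np.roll(valid, off, axis=axis)
        # pixels rolled across the frame border are not real neighbours
        in_bounds = np.ones_like(valid)
        idx = [slice(None), slice(None)]
        if off > 0:
            idx[axis] = slice(0, off)
            in_bounds[tuple(idx)] = False
        elif off < 0:
            idx[axis] = slice(off, None)
            in_bounds[tuple(idx)] = False
        ok = shifted_valid & in_bounds
        if cfg.spatial_delta > 0:
            ok = ok & (np.abs(shifted - values) <= cfg.spatial_delta)
        acc += np.where(ok, w * shifted, 0.0)
        wsum += np.where(ok, w, 0.0)
    out = np.where(valid & (wsum > 0), acc / np.where(wsum > 0, wsum, 1.0), values)
    return out


def apply_spatial_filter(depth: DepthFrame, cfg: FilterConfig) -> DepthFrame:
    """Edge-preserving spatial smoothing of a depth frame.

    ``spatial_iterations`` passes of a horizontal-then-vertical weighted
    average with truncated-exponential weights (1−alpha)^|offset| within
    ``spatial_radius``.  A neighbour whose depth differs from the centre pixel
    by more than ``spatial_delta`` mm is excluded, which preserves depth
    discontinuities (plate rims, food edges); delta 0 disables the edge
    threshold entirely (pure smoothing).  Invalid pixels neither contribute
    nor change; alpha 1 leaves the frame untouched.
    """
    values = depth.values.copy()
    for _ in range(cfg.spatial_iterations):
        values = _spatial_pass(values, depth.valid, cfg, axis=1)
        values = _spatial_pass(values, depth.valid, cfg, axis=0)
    values = np.where(depth.valid, values, 0.0)
    return DepthFrame(values, depth.valid.copy(), depth.timestamp)


def decimate_stream(
    frames: Sequence[DepthFrame], factor: int, spatial: bool = False
) -> list[DepthFrame]:
    """Decimation to speed up processing.

    Default (temporal): keep every ``factor``-th frame starting at index 0 —
    "half of the images" at factor 2.  With ``spatial=True`` instead
    subsamples every ``factor``-th pixel of every frame, the resolution-
    reduction reading common in stereo pipelines; note this scales the
    effective kpix by ``factor``.
    """
    if factor < 1:
        raise ValueError(f"decimation factor must be >= 1, got {factor}")
    if not spatial:
        return list(frames[::factor])
    return [
        DepthFrame(f.values[::factor, ::factor], f.valid[::factor, ::factor], f.timestamp)
        for f in frames
    ]


def saturate_depth(depth: DepthFrame, sat_min: float, sat_max: float) -> DepthFrame:
    """Clamp valid depths into the working band [sat_min, sat_max] mm."""
    if sat_min > sat_max:
        raise ValueError(f"sat_min {sat_min} > sat_max {sat_max}")
    out = np.where(depth.valid, np.clip(depth.values, sat_min, sat_max), 0.0)
    return DepthFrame(out, depth.valid.copy(), depth.timestamp)
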