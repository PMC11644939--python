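"""Detection and segmentation data model.

The volume pipeline is agnostic to where masks come from: a trained instance
segmenter in production, label images or polygon annotations offline, or a
colour-key segmenter on synthetic renders.  All providers produce the same
``SegmentationMask`` contract — a binary in(s,k) grid per food class, aligned
pixel-for-pixel with the depth frame — and detection gating at a confidence
threshold decides per frame whether any measurement happens at all.

Coordinate conventions: 0-based, (column u, row v), origin top-left; bounding
boxes are half-open; a pixel (u, v) has its centre at (u + 0.5, v + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "DetectionRecord",
    "SegmentationMask",
    "LabelImage",
    "GateResult",
    "gate_detections",
    "masks_from_label_image",
    "label_image_from_masks",
    "colorkey_segment",
    "mask_from_polygon",
]


@dataclass(frozen=True)
class DetectionRecord:
    """One detector output: class, half-open pixel bbox, confidence in [0, 1]."""

    class_label: str
    bbox: tuple[int, int, int, int]  # (u_min, v_min, u_max, v_max), half-open
    confidence: float
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        u0, v0, u1, v1 = self.bbox
        if not (u0 < u1 and v0 < v1):
            raise ValueError(f"degenerate bbox {self.bbox}: need u_min<u_max, v_min<v_max")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class SegmentationMask:
    """Binary per-class mask in(s,k); True marks pixels of ``class_label``."""

    class_label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class LabelImage:
    """Integer label grid with a legend mapping each nonzero id to a class."""

    grid: np.ndarray
    legend: Mapping[int, str]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must be a 2-D integer array")


@dataclass(frozen=True)
class GateResult:
    """Outcome of confidence gating for one frame.

    ``discarded`` is a recorded state, not an error: a frame with no
    above-threshold detections is skipped by the volume stage but still
    accounted for in reports.
    """

    kept: tuple[DetectionRecord, ...]
    discarded: bool
    threshold: float


def gate_detections(dets: Sequence[DetectionRecord], threshold: float = 0.5) -> GateResult:
    """Keep detections with confidence >= threshold, preserving order.

    A frame whose detections all fall below the threshold (or that has none)
    is marked discarded: low confidence would undermine segmentation and the
    volume computed from it.
    """
    kept = tuple(d for d in dets if d.confidence >= threshold)
    return GateResult(kept=kept, discarded=len(kept) == 0, threshold=threshold)


def masks_from_label_image(img: LabelImage) -> list[SegmentationMask]:
    """Split a label image into one binary mask per legend class.

    Masks are pairwise disjoint and their union is exactly the nonzero pixels.
    """
    present = np.unique(img.grid)
    present = present[present != 0]
    missing = [int(i) for i in present if int(i) not in img.legend]
    if missing:
        raise ValueError(f"label ids {missing} missing from legend {dict(img.legend)}")
    return [
        SegmentationMask(class_label=img.legend[int(i)], mask=img.grid == i) for i in present
    ]


def label_image_from_masks(
    masks: Sequence[SegmentationMask], shape: Optional[tuple[int, int]] = None
) -> LabelImage:
    """Inverse of :func:`masks_from_label_image`; masks must be disjoint."""
    if not masks and shape is None:
        raise ValueError("need an explicit shape for an empty mask list")
    shape = shape if shape is not None else masks[0].shape
    grid = np.zeros(shape, dtype=np.int32)
    legend: dict[int, str] = {}
    for i, m in enumerate(masks, start=1):
        if m.shape != shape:
            raise ValueError(f"mask shape {m.shape} != {shape}")
        if np.any(grid[m.mask] != 0):
            raise ValueError("masks overlap; cannot build a label image")
        grid[m.mask] = i
        legend[i] = m.class_label
    return LabelImage(grid=grid, legend=legend)


def colorkey_segment(
    rgb: np.ndarray,
    palette: Mapping[str, tuple[int, int, int]],
    tol: int = 0,
) -> list[SegmentationMask]:
    """Segment a synthetic render by matching pixels to known palette colours.

    A pixel joins the class whose palette colour it matches within ``tol`` in
    every channel; unmatched pixels (background, tray) belong to no mask.
    Palette colours must be pairwise separated by more than 2·tol in at least
    one channel so no pixel can match two classes.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB array, got shape {rgb.shape}")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    labels = list(palette)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            diff = np.abs(np.asarray(palette[a], dtype=int) - np.asarray(palette[b], dtype=int))
            if not np.any(diff > 2 * tol):
                raise ValueError(
                    f"palette colours for {a!r} and {b!r} are ambiguous at tol={tol}: "
                    f"every channel differs by <= {2 * tol}"
                )
    out = []
    img = rgb.astype(int)
    for label in labels:
        color = np.asarray(palette[label], dtype=int)
        hit = np.all(np.abs(img - color) <= tol, axis=2)
        if hit.any():
            out.append(SegmentationMask(class_label=label, mask=hit))
    return out


def mask_from_polygon(
    vertices: Sequence[tuple[float, float]],
    shape: tuple[int, int],
    class_label: str = "polygon",
) -> SegmentationMask:
    """Rasterize a polygon annotation with the even-odd rule.

    A pixel is set iff its centre (u + 0.5, v + 0.5) is crossed an odd number
    of times by a leftward ray (crossing-number test), matching manual contour
    annotations.  Vertices are (u, v) in pixel units.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 (u, v) vertices")
    # degenerate: zero area (all points collinear)
    x, y = verts[:, 0], verts[:, 1]
    area2 = np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area2 == 0:
        raise ValueError("degenerate polygon: zero area")
    h, w = shape
    cu = np.arange(w) + 0.5
    cv = np.arange(h) + 0.5
    uu, vv = np.meshgrid(cu, cv)
    inside = np.zeros(shape, dtype=bool)
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    for ax, ay, bx, by in zip(x, y, x1, y1):
        if ay == by:
            continue
        crosses = (ay > vv) != (by > vv)
        with np.errstate(invalid="ignore", divide="ignore"):
            xint = ax + (vv - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (uu < xint)
    return SegmentationMask(class_label=class_label, mask=inside)
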