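"""End-to-end pipeline orchestration, serving counting, and report generation.

``run_pipeline`` ties the stages together per frame: confidence gating (a
frame whose detections are all below threshold is discarded, not measured),
mask acquisition, the depth filter chain, reference-point calibration,
saturated mask-gated volume integration, and weight estimation.  Every input
frame ends in exactly one of three recorded states — measured, discarded, or
errored — and the summary aggregates per-configuration volume statistics.

``count_servings`` debounces a gated, time-ordered detection stream into
serving events: detections separated by less than a configurable gap belong
to one tray.  This counting rule is operational plumbing for the
dish-counting objective, not a published algorithm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import compute_kpix, pick_reference_depth
from .rgbd import CameraModel, DepthFrame, FilterConfig, apply_median_filter, apply_spatial_filter
from .segmentation import (
    DetectionRecord,
    LabelImage,
    SegmentationMask,
    colorkey_segment,
    gate_detections,
    masks_from_label_image,
)
from .volume import VolumeResult, compute_dish_volumes
from .weight import DensityTable, ExponentialGPR, config_stats, density_weight

log = logging.getLogger("trayvol")

__all__ = [
    "RunConfig",
    "FrameInput",
    "FrameReport",
    "PipelineReport",
    "ServingEvent",
    "count_servings",
    "run_pipeline",
    "write_report",
]


@dataclass(frozen=True)
class ServingEvent:
    start_s: float
    end_s: float
    representative_frame: str
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start_s > self.end_s:
            raise ValueError(f"event start {self.start_s} after end {self.end_s}")


def count_servings(
    dets: Sequence[tuple[str, DetectionRecord]], gap_s: float = 5.0
) -> list[ServingEvent]:
    """Debounce a time-ordered stream of (frame_id, gated detection) into servings.

    Consecutive detections separated by less than ``gap_s`` seconds merge into
    one event; a gap of ``gap_s`` or more starts a new tray.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be > 0")
    stamped = [(fid, d) for fid, d in dets if d.timestamp is not None]
    times = [d.timestamp for _, d in stamped]
    if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("detection stream is not time-sorted")
    events: list[ServingEvent] = []
    cluster: list[tuple[str, DetectionRecord]] = []
    for item in stamped:
        if cluster and item[1].timestamp - cluster[-1][1].timestamp >= gap_s:
            events.append(_close_event(cluster))
            cluster = []
        cluster.append(item)
    if cluster:
        events.append(_close_event(cluster))
    return events


def _close_event(cluster: list[tuple[str, DetectionRecord]]) -> ServingEvent:
    classes = tuple(dict.fromkeys(d.class_label for _, d in cluster))
    return ServingEvent(
        start_s=cluster[0][1].timestamp,
        end_s=cluster[-1][1].timestamp,
        representative_frame=cluster[0][0],
        classes=classes,
    )


@dataclass
class RunConfig:
    """Validated run configuration (usually loaded from a single YAML file)."""

    camera: CameraModel
    reference_point: tuple[int, int]
    reference_window: int = 2
    sat_min_mm: float = 900.0
    sat_max_mm: float = 1350.0
    flatness_tolerance_mm: float = 10.0
    filters: FilterConfig = field(default_factory=FilterConfig)
    confidence_threshold: float = 0.5
    palette: Optional[dict[str, tuple[int, int, int]]] = None
    palette_tol: int = 10
    densities: Optional[DensityTable] = None
    model_path: Optional[Path] = None
    serving_gap_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sat_min_mm > self.sat_max_mm:
            raise ValueError("sat_min_mm > sat_max_mm")
        u, v = self.reference_point
        if not (0 <= u < self.camera.width_px and 0 <= v < self.camera.height_px):
            raise ValueError(f"reference point {self.reference_point} outside frame")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cam = CameraModel(**raw["camera"])
        cal = raw.get("calibration", {})
        filters = FilterConfig(**raw.get("filters", {}))
        seg = raw.get("segmentation", {})
        palette = seg.get("palette")
        if palette is not None:
            palette = {k: tuple(v) for k, v in palette.items()}
        densities = None
        if raw.get("densities"):
            from .io import read_density_csv

            densities = read_density_csv(Path(path).parent / raw["densities"])
        model_path = raw.get("model")
        return cls(
            camera=cam,
            reference_point=tuple(cal.get("reference_point", [5, 5])),
            reference_window=cal.get("window", 2),
            sat_min_mm=cal.get("sat_min_mm", 900.0),
            sat_max_mm=cal.get("sat_max_mm", 1350.0),
            flatness_tolerance_mm=cal.get("flatness_tolerance_mm", 10.0),
            filters=filters,
            confidence_threshold=raw.get("confidence_threshold", 0.5),
            palette=palette,
            palette_tol=seg.get("tol", 10),
            densities=densities,
            model_path=None if model_path is None else Path(path).parent / model_path,
            serving_gap_s=raw.get("serving_gap_s", 5.0),
            seed=raw.get("seed", 0),
        )


@dataclass
class FrameInput:
    """One frame's inputs; masks come from a label image or colour-key on RGB."""

    frame_id: str
    depth: DepthFrame
    rgb: Optional[np.ndarray] = None
    label_image: Optional[LabelImage] = None
    detections: Optional[Sequence[DetectionRecord]] = None
    config_id: str = ""


@dataclass
class FrameReport:
    frame_id: str
    status: str  # measured | discarded | errored
    reason: str = ""
    config_id: str = ""
    volumes: list[VolumeResult] = field(default_factory=list)
    weights_g: dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineReport:
    frames: list[FrameReport]
    summary: dict

    def measured(self) -> list[FrameReport]:
        return [f for f in self.frames if f.status == "measured"]


def _frame_masks(cfg: RunConfig, frame: FrameInput) -> list[SegmentationMask]:
    if frame.label_image is not None:
        return masks_from_label_image(frame.label_image)
    if frame.rgb is not None:
        if cfg.palette is None:
            raise ValueError("RGB segmentation requested but no palette configured")
        return colorkey_segment(frame.rgb, cfg.palette, tol=cfg.palette_tol)
    raise ValueError("frame has neither a label image nor an RGB frame to segment")


def run_pipeline(cfg: RunConfig, frames: Sequence[FrameInput]) -> PipelineReport:
    """Run gate → segment → filter → calibrate → volume → weight per frame.

    Stage failures are recorded on the frame and the pipeline continues; the
    result is deterministic given config and inputs.
    """
    model = None
    if cfg.model_path is not None:
        model = ExponentialGPR.from_json(cfg.model_path)
    reports: list[FrameReport] = []
    for frame in frames:
        rep = FrameReport(frame_id=frame.frame_id, status="measured", config_id=frame.config_id)
        reports.append(rep)
        try:
            if frame.detections is not None:
                gate = gate_detections(frame.detections, cfg.confidence_threshold)
                if gate.discarded:
                    rep.status = "discarded"
                    rep.reason = (
                        f"no detection at or above confidence {cfg.confidence_threshold}"
                    )
                    log.info("frame %s discarded: %s", frame.frame_id, rep.reason)
                    continue
            masks = _frame_masks(cfg, frame)
            depth = apply_median_filter(frame.depth, cfg.filters.median_kernel)
            depth = apply_spatial_filter(depth, cfg.filters)
            ref = pick_reference_depth(
                depth, *cfg.reference_point, window=cfg.reference_window
            )
            scale = compute_kpix(cfg.camera, ref.depth_mm)
            rep.volumes = compute_dish_volumes(
                depth, masks, ref, scale, cfg.sat_min_mm, cfg.sat_max_mm
            )
            for vr in rep.volumes:
                if model is not None:
                    mean, _ = model.predict([vr.volume_mm3])
                    rep.weights_g[vr.class_label] = float(mean[0])
                elif cfg.densities is not None and vr.class_label in cfg.densities.densities:
                    rep.weights_g[vr.class_label] = density_weight(
                        vr.volume_mm3, vr.class_label, cfg.densities
                    )
        except Exception as exc:  # recorded, pipeline continues
            rep.status = "errored"
            rep.reason = str(exc)
            log.warning("frame %s errored: %s", frame.frame_id, exc)
    summary = _summarize(reports)
    return PipelineReport(frames=reports, summary=summary)


def _summarize(reports: Sequence[FrameReport]) -> dict:
    by_status = {s: sum(1 for r in reports if r.status == s) for s in ("measured", "discarded", "errored")}
    groups: dict[str, list[float]] = {}
    for r in reports:
        if r.status != "measured":
            continue
        for vr in r.volumes:
            key = f"{vr.class_label}/{r.config_id}" if r.config_id else vr.class_label
            groups.setdefault(key, []).append(vr.volume_mm3)
    stats = [s.rounded() for s in config_stats(groups)] if groups else []
    return {"frame_counts": by_status, "volume_stats": stats}


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    """Write per-frame CSV and a JSON summary under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in report.frames:
        if r.volumes:
            for vr in r.volumes:
                rows.append(
                    {
                        "frame_id": r.frame_id,
                        "status": r.status,
                        "reason": r.reason,
                        "config_id": r.config_id,
                        **vr.as_dict(),
                        "weight_g": r.weights_g.get(vr.class_label),
                    }
                )
        else:
            rows.append(
                {
                    "frame_id": r.frame_id,
                    "status": r.status,
                    "reason": r.reason,
                    "config_id": r.config_id,
                }
            )
    pd.DataFrame(rows).to_csv(out / "frames.csv", index=False)
    (out / "summary.json").write_text(json.dumps(report.summary, indent=2))
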