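"""On-disk formats.

Depth frames travel as 16-bit grayscale PNG with 1 unit = 1 mm (lossless for
the 0–65 m range) accompanied by a JSON sidecar declaring units and validity
convention, or as raw ``.npy`` arrays with the same sidecar.  Readers refuse
frames whose sidecar does not declare millimetres — silent unit drift is the
classic way to be off by 10³ in a volume.  Segmentation label images are
paletted PNGs with a JSON legend; detections and volume–weight tables are
plain CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .rgbd import DepthFrame
from .segmentation import DetectionRecord, LabelImage, SegmentationMask, masks_from_label_image
from .weight import DensityTable, VolumeWeightSet

__all__ = [
    "write_depth_png",
    "read_depth_png",
    "write_depth_raw",
    "read_depth_raw",
    "write_rgb_png",
    "read_rgb_png",
    "write_label_image",
    "read_label_image",
    "read_polygon_annotations",
    "read_detections_csv",
    "write_detections_csv",
    "read_volume_weight_csv",
    "write_volume_weight_csv",
    "read_density_csv",
]

_DEPTH_UNITS = "mm"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _check_units(sidecar: Mapping, path: Path) -> None:
    units = sidecar.get("units")
    if units != _DEPTH_UNITS:
        raise ValueError(
            f"{path}: sidecar declares units {units!r}; this pipeline only accepts 'mm'"
        )


def write_depth_png(path: str | Path, depth: DepthFrame) -> None:
    """16-bit grayscale PNG, 1 unit = 1 mm; invalid pixels stored as 0."""
    path = Path(path)
    vals = np.where(depth.valid, np.round(depth.values), 0.0)
    if np.any(vals > 65535):
        raise ValueError("depth exceeds 65535 mm; cannot store in 16-bit PNG")
    iio.imwrite(path, vals.astype(np.uint16))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "units": _DEPTH_UNITS,
                "invalid_value": 0,
                "timestamp": depth.timestamp,
                "shape": list(depth.shape),
            }
        )
    )


def read_depth_png(path: str | Path) -> DepthFrame:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    _check_units(sidecar, path)
    raw = np.asarray(iio.imread(path)).astype(float)
    valid = raw > 0
    return DepthFrame(np.where(valid, raw, 0.0), valid, timestamp=sidecar.get("timestamp"))


def write_depth_raw(path: str | Path, depth: DepthFrame) -> None:
    """Raw float array (.npy) + sidecar; preserves sub-mm precision and validity."""
    path = Path(path)
    np.save(path, np.where(depth.valid, depth.values, np.nan))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "units": _DEPTH_UNITS,
                "invalid_value": "nan",
                "timestamp": depth.timestamp,
                "shape": list(depth.shape),
            }
        )
    )


def read_depth_raw(path: str | Path) -> DepthFrame:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    _check_units(sidecar, path)
    raw = np.load(path)
    valid = np.isfinite(raw)
    return DepthFrame(np.where(valid, raw, 0.0), valid, timestamp=sidecar.get("timestamp"))


def write_rgb_png(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def read_rgb_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_label_image(path: str | Path, label: LabelImage) -> None:
    """8-bit label PNG + JSON legend sidecar (id → class)."""
    path = Path(path)
    if label.grid.max(initial=0) > 255:
        raise ValueError("more than 255 classes cannot be stored in an 8-bit label PNG")
    iio.imwrite(path, label.grid.astype(np.uint8))
    _sidecar_path(path).write_text(
        json.dumps({"legend": {str(k): v for k, v in label.legend.items()}})
    )


def read_label_image(path: str | Path) -> LabelImage:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    legend = {int(k): v for k, v in sidecar["legend"].items()}
    grid = np.asarray(iio.imread(path)).astype(np.int32)
    return LabelImage(grid=grid, legend=legend)


def read_polygon_annotations(path: str | Path) -> list[dict]:
    """JSON list of {"class": str, "vertices": [[u, v], ...]} records."""
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise ValueError(f"{path}: expected a JSON list of polygon records")
    for r in records:
        if "class" not in r or "vertices" not in r:
            raise ValueError(f"{path}: polygon record missing 'class' or 'vertices': {r}")
    return records


_DET_FIELDS = ["frame_id", "class", "u_min", "v_min", "u_max", "v_max", "confidence", "timestamp"]


def write_detections_csv(path: str | Path, rows: Sequence[tuple[str, DetectionRecord]]) -> None:
    """Rows are (frame_id, record) pairs."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_DET_FIELDS)
        for frame_id, d in rows:
            w.writerow(
                [frame_id, d.class_label, *d.bbox, d.confidence, "" if d.timestamp is None else d.timestamp]
            )


def read_detections_csv(path: str | Path) -> list[tuple[str, DetectionRecord]]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ts = row.get("timestamp") or None
            out.append(
                (
                    row["frame_id"],
                    DetectionRecord(
                        class_label=row["class"],
                        bbox=(
                            int(row["u_min"]),
                            int(row["v_min"]),
                            int(row["u_max"]),
                            int(row["v_max"]),
                        ),
                        confidence=float(row["confidence"]),
                        timestamp=None if ts is None else float(ts),
                    ),
                )
            )
    return out


def write_volume_weight_csv(path: str | Path, data: VolumeWeightSet) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "config_id", "volume_mm3", "weight_g"])
        labels = data.class_labels or [""] * len(data)
        configs = data.config_ids or [""] * len(data)
        for lab, cfg, v, g in zip(labels, configs, data.volumes_mm3, data.weights_g):
            w.writerow([lab, cfg, v, g])


def read_volume_weight_csv(path: str | Path) -> VolumeWeightSet:
    vols, wts, labels, configs = [], [], [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            vols.append(float(row["volume_mm3"]))
            wts.append(float(row["weight_g"]))
            labels.append(row.get("class", ""))
            configs.append(row.get("config_id", ""))
    return VolumeWeightSet(
        volumes_mm3=np.asarray(vols),
        weights_g=np.asarray(wts),
        class_labels=labels,
        config_ids=configs,
    )


def read_density_csv(path: str | Path) -> DensityTable:
    """CSV with columns class, density_g_per_mm3."""
    densities = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            densities[row["class"]] = float(row["density_g_per_mm3"])
    if not densities:
        raise ValueError(f"{path}: no density rows found")
    return DensityTable(densities)
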