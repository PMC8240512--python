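"""Readers and writers: VIA-2 annotation projects, CSV tables, run configs.

The VIA (VGG Image Annotator) dialect understood here is the VIA-2 project
JSON: ``_via_img_metadata`` maps an image key to ``{filename, size,
regions}``, each region being ``{"shape_attributes": {"name": "rect", x, y,
width, height}, "region_attributes": {"class": ...}}``. A bare mapping of
image keys to entries (no ``_via_img_metadata`` wrapper) is also accepted.
Only rectangular regions are meaningful for boxes; any other shape raises a
descriptive error naming the offending region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .detector import BoundingBox


@dataclass
class ViaImage:
    filename: str
    size: int
    boxes: list[BoundingBox] = field(default_factory=list)


@dataclass
class ViaProject:
    images: list[ViaImage]

    def boxes_by_filename(self) -> dict[str, list[BoundingBox]]:
        return {im.filename: im.boxes for im in self.images}

    @property
    def n_boxes(self) -> int:
        return sum(len(im.boxes) for im in self.images)


def read_via(path) -> ViaProject:
    """Parse a VIA-2 project; tolerant of missing optional attributes."""
    with open(path) as fh:
        raw = json.load(fh)
    meta = raw.get("_via_img_metadata", raw)
    images = []
    for key, entry in meta.items():
        if not isinstance(entry, dict) or "regions" not in entry:
            continue
        fname = entry.get("filename", key)
        boxes = []
        for ri, region in enumerate(entry.get("regions") or []):
            shape = region.get("shape_attributes", {})
            name = shape.get("name", "rect")
            if name != "rect":
                raise ValueError(
                    f"region {ri} of image {fname!r} has shape {name!r}; "
                    "only 'rect' regions are supported"
                )
            try:
                x, y = float(shape["x"]), float(shape["y"])
                w, h = float(shape["width"]), float(shape["height"])
            except KeyError as e:
                raise ValueError(
                    f"region {ri} of image {fname!r} lacks rect attribute {e}"
                ) from None
            if w <= 0 or h <= 0:
                raise ValueError(
                    f"region {ri} of image {fname!r} has non-positive size {w}x{h}"
                )
            label = (region.get("region_attributes") or {}).get("class", "Pod")
            boxes.append(BoundingBox(x, y, x + w, y + h, label=label))
        images.append(ViaImage(fname, int(entry.get("size", -1)), boxes))
    return ViaProject(images)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_counts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"plot_id", "true_count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns plot_id,true_count")
    return df


def write_detections_csv(path, detections_by_image: dict[str, list[BoundingBox]]) -> None:
    rows = [
        {"image_id": img, "x_min": b.x_min, "y_min": b.y_min,
         "x_max": b.x_max, "y_max": b.y_max,
         "score": b.score if b.score is not None else 1.0, "label": b.label}
        for img, boxes in detections_by_image.items()
        for b in boxes
    ]
    pd.DataFrame(rows, columns=["image_id", "x_min", "y_min", "x_max", "y_max",
                                "score", "label"]).to_csv(path, index=False)


def read_detections_csv(path) -> dict[str, list[BoundingBox]]:
    df = pd.read_csv(path)
    out: dict[str, list[BoundingBox]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.image_id), []).append(
            BoundingBox(row.x_min, row.y_min, row.x_max, row.y_max,
                        score=float(row.score),
                        label=getattr(row, "label", "Pod"))
        )
    return out


def write_estimates_csv(path, estimates) -> None:
    pd.DataFrame(
        [{"plot_id": e.plot_id, "predicted_count": e.predicted_count,
          "n_views": e.n_views_used} for e in estimates]
    ).to_csv(path, index=False)


def write_track_table(path, tracker) -> None:
    rows = []
    for t in tracker.all_tracks:
        for (f, x, y), (_, b) in zip(t.centroid_history, t.box_history):
            rows.append({"frame_idx": f, "track_id": t.track_id, "x": x, "y": y,
                         "x_min": b.x_min, "y_min": b.y_min,
                         "x_max": b.x_max, "y_max": b.y_max})
    pd.DataFrame(rows, columns=["frame_idx", "track_id", "x", "y",
                                "x_min", "y_min", "x_max", "y_max"]).to_csv(path, index=False)


def write_windows_csv(path, windows: dict[int, tuple[int, int]]) -> None:
    with open(path, "w") as fh:
        fh.write("track_id,first_frame,last_frame\n")
        for tid in sorted(windows):
            a, b = windows[tid]
            fh.write(f"{tid},{a},{b}\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ARITY_BY_REGIME = {"control": (1, 3), "infield": (2, 6)}


@dataclass
class RunConfig:
    """One YAML file drives one experiment step; see docs/methods.md."""

    paths: dict
    regime: str = "control"
    n_views: int = 3
    seed: int = 0
    synth: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    fusion: dict = field(default_factory=dict)
    tracker: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.regime not in _ARITY_BY_REGIME:
            raise ValueError(f"regime must be control or infield, got {self.regime!r}")
        if self.n_views not in _ARITY_BY_REGIME[self.regime]:
            raise ValueError(
                f"{self.regime} regime permits view arity {_ARITY_BY_REGIME[self.regime]}, "
                f"got {self.n_views}"
            )


def load_run_config(path, check_paths: bool = True) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__})
    if check_paths:
        for key, p in (cfg.paths or {}).items():
            if key.startswith(("images", "annotations", "counts", "checkpoint",
                               "detections", "estimates")) and p is not None:
                if not Path(p).exists():
                    raise FileNotFoundError(f"config path {key!r} does not exist: {p}")
    return cfg
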