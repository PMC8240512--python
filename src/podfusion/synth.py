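"""Seeded synthetic soybean plot scenes, multiview renders and pan videos.

The generator emulates the statistical structure of breeding-plot imagery:
plots of 1-10 plants bearing 100-1100 elongated pod-like objects, partial
occlusion by foliage, a clean dark backdrop (control regime) or cluttered
low-contrast vegetation (in-field regime), 1-3 views per side, and a camera
panning along a row of plots. Visual realism is not a goal; pods are textured
rotated ellipses in a brown/tan palette and plants are stem polylines.

All stochasticity flows from the single integer seed in ``SceneConfig``
through one ``numpy.random.default_rng`` stream: identical config and seed
give bit-identical images and annotations.

Pod areas are resolution-relative: the configured area range describes pods
at ``reference_width`` (full-resolution imagery) and is scaled by
``(image_width / reference_width)**2`` at render time, with a small floor so
pods never vanish at desk-scale resolutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .detector import BoundingBox

BROWN = np.array([118, 80, 38], float)
TAN = np.array([205, 178, 128], float)
LEAF_GREEN = np.array([70, 105, 48], float)
DARK_THRESHOLD = 40.0  # control backgrounds must average below this


@dataclass
class SceneConfig:
    image_width: int = 512
    image_height: int = 512
    pods_min: int = 100
    pods_max: int = 1100
    pod_area_min: float = 30.0       # px^2 at reference_width
    pod_area_max: float = 4000.0
    reference_width: int = 2048
    occlusion_fraction: float = 0.3
    background_mode: str = "control"
    views_per_side: int = 3
    sides: int = 1
    seed: int = 0
    visibility_threshold: float = 0.25

    def __post_init__(self):
        if self.pods_min > self.pods_max:
            raise ValueError("pods_min must not exceed pods_max")
        if self.pod_area_min > self.pod_area_max:
            raise ValueError("pod_area_min must not exceed pod_area_max")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        if self.background_mode not in ("control", "infield"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if self.views_per_side not in (1, 3):
            raise ValueError("views_per_side must be 1 or 3")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")

    @property
    def n_views(self) -> int:
        return self.views_per_side * self.sides

    @property
    def area_scale(self) -> float:
        return (self.image_width / self.reference_width) ** 2


@dataclass
class PodInstance:
    center: tuple[float, float]          # (x, y)
    axes: tuple[float, float]            # semi-axes (major, minor)
    angle: float                         # degrees
    depth_rank: int
    visible_fraction_per_view: list[float] = field(default_factory=list)

    def box(self, width: int, height: int) -> BoundingBox | None:
        """Axis-aligned box of the rotated ellipse, clipped to the image."""
        th = np.deg2rad(self.angle)
        a, b = self.axes
        hx = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
        hy = np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2)
        x0 = max(0.0, self.center[0] - hx)
        y0 = max(0.0, self.center[1] - hy)
        x1 = min(float(width), self.center[0] + hx)
        y1 = min(float(height), self.center[1] + hy)
        if x0 >= x1 or y0 >= y1:
            return None
        return BoundingBox(x0, y0, x1, y1, label="Pod")


@dataclass
class PlotScene:
    config: SceneConfig
    pods: list[PodInstance]
    true_count: int
    views: list[np.ndarray]                  # HxWx3 uint8 renders
    annotations: list[list[BoundingBox]]     # per view, visibility-filtered
    plot_id: str = "plot0"


@dataclass
class FrameSequence:
    frames: list[np.ndarray]
    plot_spans: list[tuple[int, int]]                       # per plot
    plot_boxes: list[list[tuple[int, BoundingBox]]]         # per frame: (plot_idx, box)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_height, cfg.image_width
    if cfg.background_mode == "control":
        # trifold dark backdrop: near-black with sensor noise
        img = np.full((h, w, 3), 16.0) + rng.normal(0, 4, size=(h, w, 3))
    else:
        # cluttered low-contrast vegetation: mid tones near the pod palette
        img = np.full((h, w, 3), 0.0) + np.array([96.0, 102.0, 78.0])
        n_blobs = max(20, (h * w) // 1500)
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry, rx = rng.uniform(3, h * 0.06), rng.uniform(3, w * 0.06)
            color = np.array([96, 102, 78]) + rng.normal(0, 28, size=3)
            rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w),
                                  rotation=rng.uniform(0, np.pi))
            img[rr, cc] = 0.6 * img[rr, cc] + 0.4 * color
        img += rng.normal(0, 6, size=(h, w, 3))
    return img


def _draw_stems(img, xs, cfg, rng):
    h = cfg.image_height
    for x in xs:
        pts_y = np.linspace(h * 0.98, h * 0.1, 12)
        drift = np.cumsum(rng.normal(0, 1.2, size=12))
        pts_x = np.clip(x + drift, 1, cfg.image_width - 2)
        for (y0, x0), (y1, x1) in zip(zip(pts_y[:-1], pts_x[:-1]), zip(pts_y[1:], pts_x[1:])):
            n = max(2, int(abs(y0 - y1)) + 1)
            ys = np.linspace(y0, y1, n).astype(int)
            xcol = np.linspace(x0, x1, n).astype(int)
            ok = (ys >= 0) & (ys < h) & (xcol >= 0) & (xcol < cfg.image_width)
            img[ys[ok], xcol[ok]] = [60, 72, 40]


def generate_plot_scene(config: SceneConfig) -> PlotScene:
    """Generate a deterministic multiview plot scene with ground truth.

    The pod count is uniform in ``[pods_min, pods_max]``. Each view renders
    the same pods (with a small per-view parallax jitter; side-2 views are
    mirrored) and applies independent foliage occluders: a pod is annotated
    in a view only when its exactly-measured visible area fraction reaches
    ``visibility_threshold``. Pod-on-pod overlap is incidental and does not
    count as occlusion.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.image_width, cfg.image_height
    n = int(rng.integers(cfg.pods_min, cfg.pods_max + 1))
    n_plants = int(min(10, max(1, np.ceil(max(n, 1) / 120))))
    stem_xs = np.sort(rng.uniform(0.12 * w, 0.88 * w, size=n_plants))

    scale = cfg.area_scale
    pod_color = BROWN if rng.random() < 0.6 else TAN  # genotype pod colour
    pods: list[PodInstance] = []
    depth = rng.permutation(n)
    for i in range(n):
        sx = stem_xs[rng.integers(0, n_plants)]
        cx = float(np.clip(sx + rng.normal(0, 0.05 * w), 0.03 * w, 0.97 * w))
        cy = float(rng.uniform(0.12 * h, 0.93 * h))
        area = max(4.0, rng.uniform(cfg.pod_area_min, cfg.pod_area_max) * scale)
        elong = rng.uniform(2.0, 3.5)
        b = np.sqrt(area / (np.pi * elong))
        a = elong * b
        pods.append(PodInstance((cx, cy), (float(a), float(b)),
                                float(rng.uniform(0, 180)), int(depth[i]), []))

    # pre-draw per-view randomness in a fixed order so the stream is stable
    views, annotations = [], []
    for v in range(cfg.n_views):
        side = v // cfg.views_per_side
        img = _background(cfg, rng)
        _draw_stems(img, stem_xs if side == 0 else w - stem_xs, cfg, rng)
        exposure = rng.uniform(0.75, 1.25)

        jx = rng.normal(0, 1.5, size=n)
        jy = rng.normal(0, 1.0, size=n)
        occluded = rng.random(n) < cfg.occlusion_fraction
        cover = rng.uniform(0.15, 0.95, size=n)
        occ_dir = rng.uniform(0, 2 * np.pi, size=n)

        order = np.argsort([p.depth_rank for p in pods])
        masks: list[tuple[np.ndarray, np.ndarray]] = [None] * n
        centers = np.empty((n, 2))
        for i in order:
            p = pods[i]
            cx = p.center[0] + jx[i]
            if side == 1:
                cx = w - cx
            cy = p.center[1] + jy[i]
            centers[i] = (cx, cy)
            rr, cc = draw_ellipse(cy, cx, p.axes[1], p.axes[0], shape=(h, w),
                                  rotation=np.deg2rad(p.angle))
            masks[i] = (rr, cc)
            shade = rng.uniform(0.85, 1.1)
            img[rr, cc] = pod_color * shade + rng.normal(0, 6, size=(rr.size, 3))

        occ_mask = np.zeros((h, w), bool)
        for i in np.where(occluded)[0]:
            p = pods[i]
            a = p.axes[0]
            d = (1.0 - cover[i]) * 2.0 * a
            ocx = centers[i, 0] + d * np.cos(occ_dir[i])
            ocy = centers[i, 1] + d * np.sin(occ_dir[i])
            rr, cc = draw_ellipse(ocy, ocx, p.axes[1] * 1.4, a * 1.2, shape=(h, w),
                                  rotation=np.deg2rad(p.angle + 30))
            img[rr, cc] = LEAF_GREEN + rng.normal(0, 5, size=(rr.size, 3))
            occ_mask[rr, cc] = True

        boxes = []
        for i, p in enumerate(pods):
            rr, cc = masks[i]
            if rr.size == 0:
                vf = 0.0
            else:
                vf = 1.0 - occ_mask[rr, cc].mean()
            p.visible_fraction_per_view.append(float(vf))
            if vf >= cfg.visibility_threshold:
                box = PodInstance(tuple(centers[i]), p.axes, p.angle, p.depth_rank).box(w, h)
                if box is not None:
                    boxes.append(box)

        img = np.clip(img * exposure, 0, 255).astype(np.uint8)
        views.append(img)
        annotations.append(boxes)

    return PlotScene(cfg, pods, n, views, annotations)


# ---------------------------------------------------------------------------
# Video sequences
# ---------------------------------------------------------------------------

def render_video_sequence(configs: list[SceneConfig], pan_speed: float = 12.0,
                          gap_fraction: float = 0.45) -> FrameSequence:
    """Pan a virtual camera left-to-right along a row of plots.

    Each config renders one plot onto a long strip (plots appear in list
    order, separated by ``gap_fraction`` of a plot width of background); the
    camera window is one plot-image wide and advances ``pan_speed`` px per
    frame. A plot's span covers exactly the frames where its ground-truth
    plant box intersects the window.
    """
    if not configs:
        raise ValueError("need at least one plot config")
    if pan_speed <= 0:
        raise ValueError("pan_speed must be positive")
    w = configs[0].image_width
    h = configs[0].image_height
    gap = int(gap_fraction * w)
    scenes = [generate_plot_scene(c) for c in configs]

    strip_w = gap + len(scenes) * (w + gap) + w  # lead-in/out of one frame width
    bg_cfg = SceneConfig(image_width=strip_w, image_height=h,
                         pods_min=0, pods_max=0,
                         background_mode=configs[0].background_mode,
                         seed=configs[0].seed + 90001)
    strip = _background(bg_cfg, np.random.default_rng(bg_cfg.seed))
    strip = np.clip(strip, 0, 255).astype(np.uint8)

    plot_boxes_strip = []
    for k, sc in enumerate(scenes):
        x0 = gap + k * (w + gap)
        strip[:, x0 : x0 + w] = sc.views[0]
        # plant extent: union of pod boxes with a margin, in strip coords
        boxes = sc.annotations[0]
        if boxes:
            bx0 = min(b.x_min for b in boxes)
            by0 = min(b.y_min for b in boxes)
            bx1 = max(b.x_max for b in boxes)
            by1 = max(b.y_max for b in boxes)
        else:
            bx0, by0, bx1, by1 = 0.1 * w, 0.1 * h, 0.9 * w, 0.95 * h
        m = 0.02 * w
        plot_boxes_strip.append((x0 + max(0, bx0 - m), max(0, by0 - m),
                                 x0 + min(w, bx1 + m), min(h, by1 + m)))

    frames, per_frame_boxes = [], []
    spans: list[list[int]] = [[None, None] for _ in scenes]
    n_frames = int(np.ceil((strip_w - w) / pan_speed)) + 1
    for f in range(n_frames):
        off = min(f * pan_speed, strip_w - w)
        xi = int(round(off))
        frames.append(strip[:, xi : xi + w].copy())
        here = []
        for k, (bx0, by0, bx1, by1) in enumerate(plot_boxes_strip):
            ix0, ix1 = max(bx0, xi), min(bx1, xi + w)
            if ix1 - ix0 > 1.0:
                here.append((k, BoundingBox(ix0 - xi, by0, ix1 - xi, by1, label="Plot")))
                if spans[k][0] is None:
                    spans[k][0] = f
                spans[k][1] = f
        per_frame_boxes.append(here)

    return FrameSequence(frames, [tuple(s) for s in spans], per_frame_boxes)


# ---------------------------------------------------------------------------
# VIA annotations and tabular ground truth
# ---------------------------------------------------------------------------

def box_to_via_region(box: BoundingBox) -> dict:
    return {
        "shape_attributes": {
            "name": "rect",
            "x": box.x_min,
            "y": box.y_min,
            "width": box.x_max - box.x_min,
            "height": box.y_max - box.y_min,
        },
        "region_attributes": {"class": box.label},
    }


def write_via_annotations(scene: PlotScene, path, image_filenames=None) -> None:
    """Write the scene's per-view annotations as a VIA-2 project JSON.

    One image entry per rendered view; regions are rects with class "Pod".
    Coordinates are written unrounded so the file round-trips losslessly
    through ``podfusion.io.read_via``.
    """
    if not scene.views:
        raise ValueError("scene has no rendered views")
    if image_filenames is None:
        image_filenames = [f"{scene.plot_id}_view{v}.png" for v in range(len(scene.views))]
    meta = {}
    for fname, boxes in zip(image_filenames, scene.annotations):
        meta[f"{fname}-1"] = {
            "filename": fname,
            "size": -1,
            "regions": [box_to_via_region(b) for b in boxes],
            "file_attributes": {},
        }
    project = {
        "_via_settings": {"project": {"name": scene.plot_id}},
        "_via_img_metadata": meta,
        "_via_attributes": {
            "region": {"class": {"type": "text", "default_value": "Pod"}},
            "file": {},
        },
    }
    with open(path, "w") as fh:
        json.dump(project, fh, indent=1, sort_keys=True)


def write_counts_csv(scenes: list[PlotScene], path) -> None:
    with open(path, "w") as fh:
        fh.write("plot_id,true_count\n")
        for s in scenes:
            fh.write(f"{s.plot_id},{s.true_count}\n")


def write_sequence_manifest(seq: FrameSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write("plot_id,first_frame,last_frame\n")
        for k, (a, b) in enumerate(seq.plot_spans):
            fh.write(f"plot{k},{a},{b}\n")
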