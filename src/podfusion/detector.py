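"""Single-class anchor-based one-stage detector for pods and plots.

The architecture follows the RetinaNet family: a VGG-style convolutional
backbone (16 conv layers in five blocks by default), a small convolutional
head predicting per-anchor objectness with a focal loss and box offsets with
a smooth-L1 loss, dense anchors on a stride lattice, and greedy NMS. The same
class serves pod detection (label "Pod") and plot detection (label "Plot");
only the training data and label differ.

Everything is desk-scale and CPU-trainable: widths default to 8-32 channels
and a single feature level is used (the pyramid level is configurable).
Coordinates are 0-based, half-open, ``(x, y) = (col, row)``, origin top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Flatten,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
    sigmoid,
)

NEGATIVE = -1
IGNORE = -2


# ---------------------------------------------------------------------------
# Boxes
# ---------------------------------------------------------------------------

@dataclass
class BoundingBox:
    """Axis-aligned pixel box, half-open ``[min, max)``, origin top-left."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float | None = None
    label: str = "Pod"

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max}): "
                "min must be strictly below max on both axes"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], float)


def boxes_to_array(boxes) -> np.ndarray:
    """List of BoundingBox -> (N,4) float array (empty-safe)."""
    if len(boxes) == 0:
        return np.zeros((0, 4))
    return np.stack([b.as_array() for b in boxes])


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) vs (M,4) half-open boxes."""
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    ix = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
        0, None,
    )
    iy = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
        0, None,
    )
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnchorConfig:
    """Anchor lattice: one entry per pyramid level used."""

    base_sizes: tuple = (16.0,)
    aspect_ratios: tuple = (0.5, 1.0, 2.0)
    scales: tuple = (1.0, 1.4, 2.0)
    strides: tuple = (8,)

    def __post_init__(self):
        if len(self.base_sizes) != len(self.strides):
            raise ValueError("base_sizes and strides must align per level")
        for v in (*self.base_sizes, *self.aspect_ratios, *self.scales, *self.strides):
            if v <= 0:
                raise ValueError("anchor geometry values must be positive")

    @property
    def anchors_per_location(self) -> int:
        return len(self.aspect_ratios) * len(self.scales)


@dataclass
class DetectorConfig:
    backbone_widths: tuple = (8, 16, 32, 32, 32)
    conv_layers_per_block: tuple = (2, 2, 4, 4, 4)
    batch_norm: bool = True
    feature_level: int = 3          # head reads the stride-2**level feature map
    head_channels: int = 32
    anchors: AnchorConfig = field(default_factory=AnchorConfig)
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    iou_pos_threshold: float = 0.5
    iou_neg_threshold: float = 0.4
    nms_iou: float = 0.5
    score_threshold: float = 0.3
    label: str = "Pod"

    def __post_init__(self):
        if isinstance(self.anchors, dict):
            self.anchors = AnchorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                           for k, v in self.anchors.items()})
        if not (0.0 <= self.iou_neg_threshold <= self.iou_pos_threshold <= 1.0):
            raise ValueError("need 0 <= iou_neg_threshold <= iou_pos_threshold <= 1")
        for t in (self.nms_iou, self.score_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if len(self.backbone_widths) != len(self.conv_layers_per_block):
            raise ValueError("one width per conv block")


# ---------------------------------------------------------------------------
# Anchors and assignment
# ---------------------------------------------------------------------------

def generate_anchors(config: AnchorConfig, image_size: tuple[int, int]) -> np.ndarray:
    """Tile anchors over the image; returns (A,4) in x_min,y_min,x_max,y_max.

    Centers sit at ``(i + 0.5) * stride``; per level the count is
    ``grid_h * grid_w * |ratios| * |scales|``.
    """
    w, h = image_size
    out = []
    for base, stride in zip(config.base_sizes, config.strides):
        gw, gh = w // stride, h // stride
        if gw < 1 or gh < 1:
            raise ValueError(f"stride {stride} leaves no grid cell in a {w}x{h} image")
        shapes = []
        for r in config.aspect_ratios:
            for s in config.scales:
                bw = base * s * np.sqrt(1.0 / r)
                bh = base * s * np.sqrt(r)
                shapes.append((bw, bh))
        shapes = np.array(shapes)
        cx = (np.arange(gw) + 0.5) * stride
        cy = (np.arange(gh) + 0.5) * stride
        cxg, cyg = np.meshgrid(cx, cy)
        centers = np.stack([cxg.ravel(), cyg.ravel()], axis=1)
        # (locations, shapes, 4), location-major to match the head layout
        a = np.empty((centers.shape[0], shapes.shape[0], 4))
        a[:, :, 0] = centers[:, None, 0] - shapes[None, :, 0] / 2
        a[:, :, 1] = centers[:, None, 1] - shapes[None, :, 1] / 2
        a[:, :, 2] = centers[:, None, 0] + shapes[None, :, 0] / 2
        a[:, :, 3] = centers[:, None, 1] + shapes[None, :, 1] / 2
        out.append(a.reshape(-1, 4))
    return np.concatenate(out, axis=0)


def match_anchors(anchors: np.ndarray, truths: np.ndarray, config: DetectorConfig) -> np.ndarray:
    """Per-anchor assignment: truth index if positive, -1 negative, -2 ignore.

    An anchor is positive when its best IoU reaches ``iou_pos_threshold``
    (ties to the lowest truth index), negative below ``iou_neg_threshold``,
    ignored in between. A truth that reaches the positive threshold with at
    least one anchor is guaranteed a positive anchor: if the argmax rule left
    it unclaimed, its best anchor is reassigned to it.
    """
    if truths.shape[0] == 0:
        return np.full(anchors.shape[0], NEGATIVE, dtype=int)
    m = iou_matrix(anchors, truths)
    best = m.max(axis=1)
    best_idx = m.argmax(axis=1)       # argmax ties -> lowest truth index
    out = np.full(anchors.shape[0], IGNORE, dtype=int)
    out[best < config.iou_neg_threshold] = NEGATIVE
    pos = best >= config.iou_pos_threshold
    out[pos] = best_idx[pos]
    claimed = set(out[pos].tolist())
    for t in range(truths.shape[0]):
        col = m[:, t]
        if t not in claimed and col.max() >= config.iou_pos_threshold:
            out[col.argmax()] = t
    return out


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def focal_loss(pred_prob, target, alpha: float = 0.25, gamma: float = 2.0):
    """Focal loss ``alpha_t * (1 - p_t)**gamma * (-log p_t)``, elementwise.

    Reduces to alpha-weighted binary cross-entropy at ``gamma == 0`` and
    vanishes in the perfect-prediction limit.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    p = np.clip(np.asarray(pred_prob, float), 1e-12, 1 - 1e-12)
    y = np.asarray(target, float)
    pt = np.where(y == 1, p, 1 - p)
    at = np.where(y == 1, alpha, 1 - alpha)
    out = at * (1 - pt) ** gamma * (-np.log(pt))
    return out if out.shape else float(out)


def _focal_grad_logits(p, y, alpha, gamma):
    """d focal / d logit, with p = sigmoid(logit). Verified numerically."""
    pt = np.where(y == 1, p, 1 - p)
    at = np.where(y == 1, alpha, 1 - alpha)
    pt = np.clip(pt, 1e-12, 1 - 1e-12)
    # dL/dpt, then dpt/dz = +-p(1-p) = pt(1-pt) with sign flip for y=0
    dL_dpt = at * ((gamma * (1 - pt) ** (gamma - 1)) * np.log(pt) - (1 - pt) ** gamma / pt) if gamma > 0 \
        else -at / pt
    dpt_dz = np.where(y == 1, 1.0, -1.0) * pt * (1 - pt)
    return dL_dpt * dpt_dz


def smooth_l1(x: np.ndarray, beta: float = 1.0 / 9.0) -> np.ndarray:
    ax = np.abs(x)
    return np.where(ax < beta, 0.5 * x * x / beta, ax - 0.5 * beta)


def _smooth_l1_grad(x: np.ndarray, beta: float = 1.0 / 9.0) -> np.ndarray:
    return np.where(np.abs(x) < beta, x / beta, np.sign(x))


# ---------------------------------------------------------------------------
# NMS
# ---------------------------------------------------------------------------

def nms(detections: list[BoundingBox], nms_iou: float) -> list[BoundingBox]:
    """Greedy NMS by descending score; score ties keep insertion order."""
    if not detections:
        return []
    scores = np.array([d.score for d in detections], float)
    order = np.argsort(-scores, kind="stable")
    arr = boxes_to_array(detections)
    kept: list[int] = []
    for i in order:
        if not kept or (iou_matrix(arr[i : i + 1], arr[kept])[0] <= nms_iou).all():
            kept.append(int(i))
    return [detections[i] for i in kept]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def build_backbone(config: DetectorConfig, rng: np.random.Generator) -> list[Sequential]:
    """VGG-pattern conv blocks; block i ends in a 2x2 max pool (stride 2**(i+1))."""
    blocks = []
    in_ch = 3
    for width, n_conv in zip(config.backbone_widths, config.conv_layers_per_block):
        layers = []
        for _ in range(n_conv):
            layers.append(Conv2d(in_ch, width, rng=rng))
            if config.batch_norm:
                layers.append(BatchNorm2d(width))
            layers.append(ReLU())
            in_ch = width
        layers.append(MaxPool2d())
        blocks.append(Sequential(*layers))
    return blocks


class Detector:
    """Anchor detector: backbone blocks + shared conv trunk + cls/reg heads."""

    def __init__(self, config: DetectorConfig | None = None, seed: int = 0):
        self.config = config or DetectorConfig()
        rng = np.random.default_rng(seed)
        self.backbone = build_backbone(self.config, rng)
        c = self.config
        feat_ch = c.backbone_widths[c.feature_level - 1]
        a = c.anchors.anchors_per_location
        self.trunk = Sequential(Conv2d(feat_ch, c.head_channels, rng=rng), ReLU())
        self.cls_head = Conv2d(c.head_channels, a, rng=rng)
        self.reg_head = Conv2d(c.head_channels, 4 * a, rng=rng)
        # rare-object prior: start the classifier near p=0.01
        self.cls_head.b[:] = -np.log(99.0)
        self._anchor_cache: dict[tuple[int, int], np.ndarray] = {}

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        return [*self.backbone, self.trunk, self.cls_head, self.reg_head]

    def train(self):
        for m in self._modules():
            m.train()

    def eval(self):
        for m in self._modules():
            m.eval()

    def zero_grad(self):
        for m in self._modules():
            m.zero_grad()

    def anchors_for(self, image_size: tuple[int, int]) -> np.ndarray:
        if image_size not in self._anchor_cache:
            self._anchor_cache[image_size] = generate_anchors(self.config.anchors, image_size)
        return self._anchor_cache[image_size]

    # -- forward/backward --------------------------------------------------
    def backbone_features(self, x: np.ndarray, level: int) -> np.ndarray:
        for blk in self.backbone[:level]:
            x = blk.forward(x)
        return x

    def forward(self, x: np.ndarray):
        feat = self.backbone_features(x, self.config.feature_level)
        t = self.trunk.forward(feat)
        return self.cls_head.forward(t), self.reg_head.forward(t)

    def backward(self, g_cls: np.ndarray, g_reg: np.ndarray):
        g = self.cls_head.backward(g_cls) + self.reg_head.backward(g_reg)
        g = self.trunk.backward(g)
        for blk in reversed(self.backbone[: self.config.feature_level]):
            g = blk.backward(g)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, blk in enumerate(self.backbone):
            for k, v in blk.named_params().items():
                out[f"backbone.{i}.{k}"] = v
        for name, mod in (("trunk", self.trunk),):
            for k, v in mod.named_params().items():
                out[f"{name}.{k}"] = v
        for name, mod in (("cls", self.cls_head), ("reg", self.reg_head)):
            for k, v in mod.params().items():
                out[f"{name}.{k}"] = v
        return out

    def load_state_dict(self, state) -> None:
        for i, blk in enumerate(self.backbone):
            blk.load_params({k.split(".", 2)[2]: v for k, v in state.items()
                             if k.startswith(f"backbone.{i}.")})
        self.trunk.load_params({k.split(".", 1)[1]: v for k, v in state.items()
                                if k.startswith("trunk.")})
        for name, mod in (("cls", self.cls_head), ("reg", self.reg_head)):
            for k in mod.params():
                mod.params()[k][...] = state[f"{name}.{k}"]


def save_checkpoint(path, model: Detector) -> None:
    """Single-file .npz checkpoint with the config embedded as JSON."""
    cfg = asdict(model.config)
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> Detector:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]).decode())
        for k in ("backbone_widths", "conv_layers_per_block"):
            cfg[k] = tuple(cfg[k])
        model = Detector(DetectorConfig(**cfg))
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return model


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def _prep_image(image: np.ndarray) -> np.ndarray:
    """HWC uint8/float -> (1,3,H,W) float64 centred on 0."""
    x = np.asarray(image, float)
    if x.max() > 1.5:
        x = x / 255.0
    return (x - 0.5).transpose(2, 0, 1)[None]


def _encode_boxes(anchors: np.ndarray, truths: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    tw = truths[:, 2] - truths[:, 0]
    th = truths[:, 3] - truths[:, 1]
    tcx = truths[:, 0] + tw / 2
    tcy = truths[:, 1] + th / 2
    return np.stack([(tcx - acx) / aw, (tcy - acy) / ah,
                     np.log(tw / aw), np.log(th / ah)], axis=1)


def _decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    d = np.clip(deltas, -4.0, 4.0)
    cx = acx + d[:, 0] * aw
    cy = acy + d[:, 1] * ah
    w = aw * np.exp(d[:, 2])
    h = ah * np.exp(d[:, 3])
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def _training_samples(scenes):
    """Accept PlotScene objects or (image, [BoundingBox]) pairs."""
    samples = []
    for s in scenes:
        if hasattr(s, "views"):
            for img, ann in zip(s.views, s.annotations):
                samples.append((img, ann))
        else:
            samples.append(s)
    return samples


def train_detector(scenes, config: DetectorConfig | None = None, epochs: int = 20,
                   seed: int = 0, lr: float = 1e-3):
    """Train on annotated scenes; returns ``(model, loss_trace)``.

    Loss per image is focal classification over all non-ignored anchors plus
    smooth-L1 box regression over positives, both normalised by the positive
    count. The trace holds one mean loss per epoch and is deterministic for a
    fixed seed.
    """
    config = config or DetectorConfig()
    samples = _training_samples(scenes)
    if not samples or all(len(ann) == 0 for _, ann in samples):
        raise ValueError("training requires at least one annotated box")
    model = Detector(config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = Adam(model._modules(), lr=lr)

    # anchors/assignments are static per sample: precompute
    prepped = []
    for img, ann in samples:
        h, w = np.asarray(img).shape[:2]
        anchors = model.anchors_for((w, h))
        truths = boxes_to_array(ann)
        assign = match_anchors(anchors, truths, config)
        reg_t = np.zeros((anchors.shape[0], 4))
        pos = assign >= 0
        if pos.any():
            reg_t[pos] = _encode_boxes(anchors[pos], truths[assign[pos]])
        prepped.append((_prep_image(img), assign, reg_t))

    model.train()
    trace = []
    a_loc = config.anchors.anchors_per_location
    for _ in range(epochs):
        order = rng.permutation(len(prepped))
        losses = []
        for i in order:
            x, assign, reg_t = prepped[i]
            cls_out, reg_out = model.forward(x)
            n, A, hh, ww = cls_out.shape
            # head layout (1, A, h, w) -> anchor-major (h*w*A,) matching generate_anchors
            logits = cls_out.transpose(0, 2, 3, 1).reshape(-1)
            p = sigmoid(logits)
            y = (assign >= 0).astype(float)
            valid = assign != IGNORE
            n_pos = max(1, int((assign >= 0).sum()))
            cls_l = focal_loss(p[valid], y[valid], config.focal_alpha, config.focal_gamma).sum() / n_pos

            deltas = reg_out.transpose(0, 2, 3, 1).reshape(-1, 4)
            pos = assign >= 0
            diff = deltas[pos] - reg_t[pos]
            reg_l = smooth_l1(diff).sum() / n_pos
            losses.append(cls_l + reg_l)

            g_log = np.zeros_like(logits)
            g_log[valid] = _focal_grad_logits(p[valid], y[valid],
                                              config.focal_alpha, config.focal_gamma) / n_pos
            g_cls = g_log.reshape(n, hh, ww, A).transpose(0, 3, 1, 2)
            g_del = np.zeros_like(deltas)
            g_del[pos] = _smooth_l1_grad(diff) / n_pos
            g_reg = g_del.reshape(n, hh, ww, 4 * A).transpose(0, 3, 1, 2)

            model.zero_grad()
            model.backward(g_cls, g_reg)
            opt.step()
        trace.append(float(np.mean(losses)))
    return model, trace


def detect(model: Detector, image: np.ndarray, config: DetectorConfig | None = None) -> list[BoundingBox]:
    """Run the detector on one HWC image; returns scored, NMS-filtered boxes.

    Boxes are clipped to the image; only scores at or above
    ``score_threshold`` survive.
    """
    config = config or model.config
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    anchors = model.anchors_for((w, h))
    model.eval()
    cls_out, reg_out = model.forward(_prep_image(img))
    scores = sigmoid(cls_out.transpose(0, 2, 3, 1).reshape(-1))
    deltas = reg_out.transpose(0, 2, 3, 1).reshape(-1, 4)
    keep = np.where(scores >= config.score_threshold)[0]
    if keep.size == 0:
        return []
    if keep.size > 2000:   # pre-NMS candidate cap, highest scores first
        keep = keep[np.argsort(-scores[keep], kind="stable")[:2000]]
    boxes = _decode_boxes(anchors[keep], deltas[keep])
    boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, w)
    boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, h)
    dets = [
        BoundingBox(*b, score=float(s), label=config.label)
        for b, s in zip(boxes, scores[keep])
        if b[0] < b[2] and b[1] < b[3]
    ]
    return nms(dets, config.nms_iou)
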