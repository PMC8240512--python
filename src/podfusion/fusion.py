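"""Multiview pod-count regression: frozen detector features + fusion head.

The count estimator reuses the trained detector's convolutional backbone as a
frozen feature-extraction module (FM). Features from the 1-6 views of a plot
are concatenated channel-wise and fed to a regression module (RM) of three
convolution layers — the first two followed by max-pooling and batch
normalisation — then a flatten layer and three fully connected layers ending
in the scalar plot pod count. Only the RM trains; the FM weights (and batch
statistics) never move.

View arity is fixed per trained model: a 3-view model will not accept a
1-view set and vice versa — there is no silent padding. For two-sided
(in-field) sets the north-side images occupy the leading channel blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, BatchNorm2d, Conv2d, Flatten, Linear, MaxPool2d, ReLU, Sequential
from .detector import Detector, DetectorConfig, build_backbone

_SIDE_ORDER = {"north": 0, "none": 1, "south": 2}


@dataclass
class ViewSet:
    """The 1-6 images of one plot fed to the regressor, side-labelled."""

    plot_id: str
    images: list
    side_labels: list[str] | None = None

    def __post_init__(self):
        if self.side_labels is None:
            self.side_labels = ["none"] * len(self.images)
        if len(self.images) not in (1, 2, 3, 6):
            raise ValueError(f"view set must hold 1, 2, 3 or 6 images, got {len(self.images)}")
        if len(self.side_labels) != len(self.images):
            raise ValueError("one side label per image")
        bad = set(self.side_labels) - set(_SIDE_ORDER)
        if bad:
            raise ValueError(f"unknown side labels {bad}")
        n_n = self.side_labels.count("north")
        n_s = self.side_labels.count("south")
        if (n_n or n_s) and n_n != n_s:
            raise ValueError("two-sided sets need equal view counts per side")

    def ordered_images(self) -> list:
        """Images in the fixed fusion order: north block first, then south."""
        idx = sorted(range(len(self.images)),
                     key=lambda i: (_SIDE_ORDER[self.side_labels[i]], i))
        return [self.images[i] for i in idx]

    @property
    def n_views(self) -> int:
        return len(self.images)


@dataclass
class FusionConfig:
    fm_frozen: bool = True
    rm_conv_channels: tuple = (256, 128, 64)
    rm_fc_widths: tuple = (256, 64, 1)
    loss: str = "mse"
    epochs: int = 150
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    standardize_features: bool = False
    seed: int = 0
    include_final_pool: bool = False
    batch_size: int = 8

    def __post_init__(self):
        if len(self.rm_conv_channels) != 3 or len(self.rm_fc_widths) != 3:
            raise ValueError("RM shape is fixed: exactly 3 conv channels and 3 FC widths")
        if self.rm_fc_widths[-1] != 1:
            raise ValueError("final FC width must be 1 (scalar count)")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if not self.fm_frozen:
            raise ValueError("the feature extractor must stay frozen during RM training")


@dataclass
class CountEstimate:
    plot_id: str
    predicted_count: float
    n_views_used: int


# ---------------------------------------------------------------------------
# Feature extraction (FM)
# ---------------------------------------------------------------------------

def extract_features(backbone, image, include_final_pool: bool = False) -> np.ndarray:
    """Frozen forward pass of the full conv stack; returns a (C,h,w) map.

    ``backbone`` is a trained :class:`~podfusion.detector.Detector` or its
    block list. With ``include_final_pool`` the map is downsampled by every
    pooling stage (512 -> 16 for the 5-block default); without it the final
    pool is skipped, keeping twice the spatial resolution.
    """
    if backbone is None:
        raise ValueError("a trained detector backbone is required")
    blocks = backbone.backbone if isinstance(backbone, Detector) else backbone
    img = np.asarray(image, float)
    if img.max() > 1.5:
        img = img / 255.0
    x = (img - 0.5).transpose(2, 0, 1)[None]
    for blk in blocks:
        blk.eval()
    for blk in blocks[:-1]:
        x = blk.forward(x)
    last = blocks[-1].layers
    if not include_final_pool and isinstance(last[-1], MaxPool2d):
        last = last[:-1]
    for layer in last:
        x = layer.forward(x)
    return x[0]


def fuse_views(feature_maps: list[np.ndarray]) -> np.ndarray:
    """Channel-wise concatenation of per-view (C,h,w) maps, view order kept."""
    shapes = {m.shape[1:] for m in feature_maps}
    if len(shapes) != 1:
        raise ValueError(f"feature maps disagree on spatial size: {sorted(shapes)}")
    return np.concatenate(feature_maps, axis=0)


# ---------------------------------------------------------------------------
# Regression module (RM)
# ---------------------------------------------------------------------------

def build_rm(in_channels: int, config: FusionConfig, rng) -> Sequential:
    """conv1>pool>norm, conv2>pool>norm, conv3, flatten, FC x3 -> scalar."""
    c1, c2, c3 = config.rm_conv_channels
    return Sequential(
        Conv2d(in_channels, c1, rng=rng), MaxPool2d(), BatchNorm2d(c1), ReLU(),
        Conv2d(c1, c2, rng=rng), MaxPool2d(), BatchNorm2d(c2), ReLU(),
        Conv2d(c2, c3, rng=rng), ReLU(),
        Flatten(),
    )


def _build_fc(rm: Sequential, n_flat: int, config: FusionConfig, rng) -> None:
    f1, f2, f3 = config.rm_fc_widths
    rm.layers += [Linear(n_flat, f1, rng=rng), ReLU(),
                  Linear(f1, f2, rng=rng), ReLU(),
                  Linear(f2, f3, rng=rng)]


def rm_layer_counts(rm: Sequential) -> dict[str, int]:
    out: dict[str, int] = {}
    for l in rm.layers:
        name = type(l).__name__
        if name != "ReLU":
            out[name] = out.get(name, 0) + 1
    return out


def rm_parameter_counts(rm: Sequential) -> list[int]:
    """Parameter count per parameterised layer, in network order."""
    return [sum(p.size for p in l.params().values()) for l in rm.layers if l.params()]


class FusionModel:
    """Frozen FM + trained RM; fixed view arity; scalar count output."""

    def __init__(self, backbone, detector_config: DetectorConfig,
                 config: FusionConfig, n_views: int, count_scale: float = 1000.0):
        self.backbone = backbone
        self.detector_config = detector_config
        self.config = config
        self.n_views = n_views
        self.count_scale = count_scale
        self.rm: Sequential | None = None
        # per-channel standardisation of the fused FM features, fitted on the
        # training set; identity until train_regressor fills it in
        self.feat_mean: np.ndarray | float = 0.0
        self.feat_std: np.ndarray | float = 1.0

    @classmethod
    def from_detector(cls, detector: Detector, config: FusionConfig, n_views: int):
        return cls(detector.backbone, detector.config, config, n_views)

    def features_for(self, view_set: ViewSet) -> np.ndarray:
        maps = [extract_features(self.backbone, img, self.config.include_final_pool)
                for img in view_set.ordered_images()]
        return fuse_views(maps)

    def _ensure_rm(self, fused_shape, rng) -> None:
        if self.rm is not None:
            return
        c, h, w = fused_shape
        self.rm = build_rm(c, self.config, rng)
        h3, w3 = h // 2 // 2, w // 2 // 2
        _build_fc(self.rm, self.config.rm_conv_channels[2] * h3 * w3, self.config, rng)

    def predict_scaled(self, fused_batch: np.ndarray) -> np.ndarray:
        self.rm.eval()
        x = (fused_batch - self.feat_mean) / self.feat_std
        return self.rm.forward(x)[:, 0]


def estimate_plot_count(model: FusionModel, view_set: ViewSet) -> CountEstimate:
    """Deterministic inference for one plot; the count is clamped to >= 0."""
    if view_set.n_views != model.n_views:
        raise ValueError(
            f"model expects {model.n_views} views, got {view_set.n_views}; "
            "no silent padding is performed"
        )
    if model.rm is None:
        raise ValueError("regression module has not been trained")
    fused = model.features_for(view_set)
    raw = float(model.predict_scaled(fused[None])[0]) * model.count_scale
    return CountEstimate(view_set.plot_id, max(0.0, raw), view_set.n_views)


def train_regressor(view_sets: list[ViewSet], true_counts, config: FusionConfig,
                    detector: Detector):
    """Train the RM on frozen fused features; returns ``(model, loss_trace)``.

    Per-view FM features are computed once and cached — the FM never enters
    the optimisation, which is what keeps it bit-identical across training.
    The targets are scaled to unit magnitude internally; the trace holds one
    mean loss per epoch on that scale and is deterministic for a fixed seed.
    """
    counts = np.asarray(true_counts, float)
    if len(view_sets) != counts.size:
        raise ValueError("one true count per view set")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    arities = {vs.n_views for vs in view_sets}
    if len(arities) != 1:
        raise ValueError(f"mixed view arities in training set: {sorted(arities)}")

    model = FusionModel.from_detector(detector, config, arities.pop())
    for blk in model.backbone:   # clear stale detector-phase gradients; the
        blk.zero_grad()          # FM is excluded from the RM optimisation
    model.count_scale = float(max(counts.max(), 1.0))
    rng = np.random.default_rng(config.seed)
    feats = np.stack([model.features_for(vs) for vs in view_sets])
    if config.standardize_features:
        model.feat_mean = feats.mean(axis=(0, 2, 3), keepdims=True)[0]
        model.feat_std = feats.std(axis=(0, 2, 3), keepdims=True)[0] + 1e-6
    feats = (feats - model.feat_mean) / model.feat_std
    model._ensure_rm(feats.shape[1:], rng)
    y = counts / model.count_scale

    opt = Adam([model.rm], lr=config.learning_rate,
               weight_decay=config.weight_decay)
    n = feats.shape[0]
    bs = min(config.batch_size, n)
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        model.rm.train()
        for s in range(0, n, bs):
            idx = order[s : s + bs]
            pred = model.rm.forward(feats[idx])[:, 0]
            diff = pred - y[idx]
            if config.loss == "mse":
                losses.append(float(np.mean(diff**2)))
                g = 2.0 * diff / idx.size
            else:
                losses.append(float(np.mean(np.abs(diff))))
                g = np.sign(diff) / idx.size
            model.rm.zero_grad()
            model.rm.backward(g[:, None])
            opt.step()
        trace.append(float(np.mean(losses)))
    return model, trace


# ---------------------------------------------------------------------------
# Checkpoints and scene plumbing
# ---------------------------------------------------------------------------

def viewset_from_scene(scene, n_views: int | None = None) -> ViewSet:
    """Build a ViewSet from a synthetic scene (north/south for 2-sided)."""
    cfg = scene.config
    views = scene.views if n_views is None else scene.views[:n_views]
    if cfg.sides == 2 and n_views is None:
        labels = ["north"] * cfg.views_per_side + ["south"] * cfg.views_per_side
    else:
        labels = ["none"] * len(views)
    return ViewSet(scene.plot_id, list(views), labels)


def save_fusion_checkpoint(path, model: FusionModel) -> None:
    import json
    from dataclasses import asdict

    meta = {
        "detector_config": asdict(model.detector_config),
        "fusion_config": asdict(model.config),
        "n_views": model.n_views,
        "count_scale": model.count_scale,
    }
    state = {"feat_mean": np.asarray(model.feat_mean, float),
             "feat_std": np.asarray(model.feat_std, float)}
    for i, blk in enumerate(model.backbone):
        for k, v in blk.named_params().items():
            state[f"fm.{i}.{k}"] = v
    for k, v in model.rm.named_params().items():
        state[f"rm.{k}"] = v
    np.savez(path, __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_fusion_checkpoint(path) -> FusionModel:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["__config__"]).decode())
        dcfg = meta["detector_config"]
        for k in ("backbone_widths", "conv_layers_per_block"):
            dcfg[k] = tuple(dcfg[k])
        fcfg = meta["fusion_config"]
        for k in ("rm_conv_channels", "rm_fc_widths"):
            fcfg[k] = tuple(fcfg[k])
        det_config = DetectorConfig(**dcfg)
        config = FusionConfig(**fcfg)
        backbone = build_backbone(det_config, np.random.default_rng(0))
        for i, blk in enumerate(backbone):
            blk.load_params({k.split(".", 2)[2]: z[k] for k in z.files
                             if k.startswith(f"fm.{i}.")})
        model = FusionModel(backbone, det_config, config,
                            meta["n_views"], meta["count_scale"])
        rng = np.random.default_rng(config.seed)
        rm_state = {k.split(".", 1)[1]: z[k] for k in z.files if k.startswith("rm.")}
        # rebuild the RM skeleton from the stored conv1 weight shape
        c_in = rm_state["0.W"].shape[1] // 9
        n_flat = rm_state["11.W"].shape[1]
        model.rm = build_rm(c_in, config, rng)
        _build_fc(model.rm, n_flat, config, rng)
        model.rm.load_params(rm_state)
        if "feat_mean" in z.files:
            model.feat_mean = z["feat_mean"]
            model.feat_std = z["feat_std"]
    return model
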