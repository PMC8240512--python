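"""Shared fixtures: desk-scale scenes and trained models, reused across files.

The expensive fixtures are session-scoped so the detector is trained once
and shared by the detector, fusion and acceptance tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from podfusion.detector import DetectorConfig, train_detector
from podfusion.synth import SceneConfig, generate_plot_scene

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# Published selection-confusion benchmark: four model variants x two culling
# levels on 51 control / 45 in-field test plots, with the reported metrics.
SELECTION_BENCHMARK = [
    # (model, fraction, tp, tn, fp, fn, accuracy, sensitivity, specificity)
    ("1img-control", 0.20, 7, 37, 3, 4, 0.86, 0.64, 0.93),
    ("1img-control", 0.30, 12, 33, 3, 3, 0.88, 0.80, 0.92),
    ("3img-control", 0.20, 7, 37, 3, 4, 0.86, 0.64, 0.93),
    ("3img-control", 0.30, 10, 31, 5, 5, 0.80, 0.67, 0.86),
    ("1img-infield", 0.20, 4, 31, 5, 5, 0.78, 0.44, 0.86),
    ("1img-infield", 0.30, 6, 25, 7, 7, 0.69, 0.46, 0.78),
    ("3img-infield", 0.20, 4, 31, 5, 5, 0.78, 0.44, 0.86),
    ("3img-infield", 0.30, 8, 27, 5, 5, 0.78, 0.62, 0.84),
]


def detection_scene_config(seed: int, **kw) -> SceneConfig:
    """Detection-friendly desk scene: few, large, well-separated pods."""
    base = dict(image_width=128, image_height=128, pods_min=40, pods_max=80,
                pod_area_min=1500, pod_area_max=6000, reference_width=512,
                occlusion_fraction=0.2, views_per_side=1, seed=seed)
    base.update(kw)
    return SceneConfig(**base)


def counting_scene_config(seed: int, **kw) -> SceneConfig:
    """Counting-regime desk scene: 100-1100 small pods, heavy occlusion."""
    base = dict(image_width=128, image_height=128, pods_min=100, pods_max=1100,
                occlusion_fraction=0.5, views_per_side=3, seed=seed)
    base.update(kw)
    return SceneConfig(**base)


@pytest.fixture(scope="session")
def overfit_scene():
    """One 64-pod, occlusion-free scene used for overfit sanity checks."""
    cfg = detection_scene_config(11, pods_min=64, pods_max=64, occlusion_fraction=0.0)
    return generate_plot_scene(cfg)


@pytest.fixture(scope="session")
def overfit_detector(overfit_scene):
    model, trace = train_detector(
        [(overfit_scene.views[0], overfit_scene.annotations[0])],
        DetectorConfig(), epochs=200, seed=0, lr=2e-3,
    )
    return model, trace


@pytest.fixture(scope="session")
def desk_detector():
    """Detector trained briefly on 8 desk scenes; the frozen FM for fusion."""
    scenes = [generate_plot_scene(detection_scene_config(100 + i)) for i in range(8)]
    model, trace = train_detector(scenes, DetectorConfig(), epochs=12, seed=0, lr=2e-3)
    return model, trace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
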