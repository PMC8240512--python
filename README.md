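# podfusion

Multiview image-fusion pod counting and genotype yield ranking for soybean
breeding plots — with a seeded synthetic plot-scene generator so the entire
pipeline is testable end-to-end on a laptop, with no field imagery.

## The problem

Soybean breeding programs advance only the top fraction (typically 20–30%)
of test plots each season, and the ranking signal — seed yield — normally
requires machine-harvesting tens of thousands of plots. Pod count is a
strong yield proxy (seed yield ≈ pod count × seeds-per-pod, with ≈2.0–2.2
seeds/pod at maturity), and pods are visible to an RGB camera on a ground
robot. The catch is occlusion: a single view of a plot hides a large share
of its pods, so per-image detection undercounts badly.

`podfusion` implements a detection-plus-fusion pipeline for this setting:

1. **Detector** (`podfusion.detector`) — a single-class, anchor-based,
   one-stage detector in the RetinaNet family: a VGG-pattern convolutional
   backbone (16 conv layers in five blocks), dense anchors on a stride
   lattice, focal classification loss
   `FL(p_t) = −α_t (1 − p_t)^γ log(p_t)` (defaults α = 0.25, γ = 2) and
   smooth-L1 box regression, greedy NMS. The same class detects pods in
   still views and whole plots in video frames.
2. **Fusion regressor** (`podfusion.fusion`) — the count estimator. The
   trained detector's conv stack becomes a *frozen* feature-extraction
   module (FM); features from the 1–6 views of a plot are concatenated
   channel-wise and a regression module (RM: conv→pool→norm ×2, conv,
   flatten, FC ×3) maps them to the scalar plot pod count. Only the RM
   trains.
3. **Tracker** (`podfusion.tracker`) — centroid tracking of plot detections
   across pan-video frames (greedy global-minimum Euclidean matching, new
   IDs for unmatched detections, retirement after 5 consecutive missed
   frames), so each plot is counted exactly once.
4. **Evaluation** (`podfusion.evaluation`) — AP/mAP at IoU 0.5 with
   all-points PR interpolation, count-agreement statistics (Pearson r, MAE,
   dispersion ratio), and the breeding-selection analysis: confusion counts
   and accuracy/sensitivity/specificity of selecting the top-k plots by
   predicted vs true count, plus the pods→seeds conversion.
5. **Synthetic scenes** (`podfusion.synth`) — seeded generator of plots
   (1–10 plants, 100–1100 elongated brown/tan pods, partial foliage
   occlusion, dark-backdrop *control* vs cluttered *in-field* regimes,
   1–3 views per side, pan-video sequences) with exact per-view visibility
   bookkeeping and VIA-2 annotation export.

All deep-learning components are implemented in NumPy inside the package
(`podfusion/_nn.py`), with analytic backward passes that are
gradient-checked in the test suite; everything trains on one CPU at desk
scale in minutes.

## Worked example

```python
import numpy as np
from podfusion import (SceneConfig, generate_plot_scene, DetectorConfig,
                       train_detector, FusionConfig, train_regressor,
                       estimate_plot_count, count_agreement, ranking_report)
from podfusion.fusion import viewset_from_scene

# detector pretraining on detection-friendly scenes
det_scenes = [generate_plot_scene(SceneConfig(
    image_width=128, image_height=128, pods_min=40, pods_max=80,
    pod_area_min=1500, pod_area_max=6000, reference_width=512,
    occlusion_fraction=0.2, views_per_side=1, seed=100 + i)) for i in range(8)]
detector, _ = train_detector(det_scenes, DetectorConfig(), epochs=12, lr=2e-3)

# multiview count regression on heavily occluded plots
def plot(seed):
    return generate_plot_scene(SceneConfig(
        image_width=128, image_height=128, pods_min=100, pods_max=1100,
        occlusion_fraction=0.5, views_per_side=3, seed=seed))

train = [plot(1000 + i) for i in range(60)]
test = [plot(5000 + i) for i in range(16)]
cfg = FusionConfig(rm_conv_channels=(64, 48, 32), rm_fc_widths=(64, 32, 1))
model, _ = train_regressor([viewset_from_scene(s) for s in train],
                           [s.true_count for s in train], cfg, detector)
preds = np.array([estimate_plot_count(model, viewset_from_scene(s)).predicted_count
                  for s in test])
truth = np.array([float(s.true_count) for s in test])
print(count_agreement(preds, truth))
print(ranking_report(preds, truth, 0.3))
```

Printed by one run of this script (≈90 s on one CPU):

```
CountAgreement(pearson_r=0.9180350122055823, mae=142.8685949609236, std_ratio=0.7241353303957373, n=16)
RankingReport(selection_fraction=0.3, k_selected=5, counts=ConfusionCounts(tp=4, tn=10, fp=1, fn=1), accuracy=0.88, sensitivity=0.8, specificity=0.91)
```

Read: the fused 3-view estimates correlate r ≈ 0.92 with the true per-plot
pod counts on 16 held-out plots, with a mean absolute error of ≈143 pods on
counts spanning 100–1100, and the estimates are under-dispersed
(std_ratio < 1 — regression to the mean, expected with mean-heavy training
data; run-to-run spread across detector seeds is substantial, see
docs/methods.md). Selecting the top 30% of plots by estimated count
recovers 4 of the 5 truly best plots (sensitivity 0.80).

A shell interface mirrors the library
(`podfusion simulate|train-detector|detect|train-fusion|estimate|track|
evaluate|rank`, each with `--config experiment.yaml --seed N --out PATH`
and presets `control-1v|control-3v|infield-1v|infield-3v`); every
invocation writes a JSON manifest for reproduction.

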