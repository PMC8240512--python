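# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the test suite demonstrates.

## Detection model

A single-class, anchor-based one-stage detector. The backbone is a
VGG-pattern stack: five blocks of 3×3 stride-1 convolutions
(2, 2, 4, 4, 4 layers per block — 16 conv layers total), each block ending
in a 2×2 max pool, so block *i* has stride 2^i. Widths are configurable;
the desk-scale default is (8, 16, 32, 32, 32) channels. Each convolution is
followed by batch normalisation and ReLU. Plain unnormalised VGG stacks are
notoriously hard to train from a cold start with small-batch CPU
optimisation, so normalisation is on by default (`batch_norm=False`
restores the plain stack); this is a trainability choice, not a change to
the architecture family.

The detection head reads a single feature level (default: after block 3,
stride 8 — synthetic pods occupy a narrow scale band, so a full pyramid
buys nothing at desk scale) through a shared 3×3 conv trunk and two 3×3
output convolutions: per-anchor objectness logits and 4 box offsets.
Anchors tile the stride lattice at one base size (16 px) × 3 aspect ratios
(0.5, 1, 2) × 3 scales (1, 1.4, 2); centers sit at `(i + 0.5)·stride`.

Training:

* assignment — an anchor is positive when its best IoU against the ground
  truth reaches 0.5, negative below 0.4, ignored between (ties to the
  lowest truth index). A truth whose best anchor reaches 0.5 but was
  claimed by another truth gets that anchor reassigned, so every reachable
  truth owns at least one positive anchor.
* classification — focal loss `−α_t (1−p_t)^γ log p_t` with α = 0.25,
  γ = 2 over all non-ignored anchors, normalised by the positive count.
  α follows the α_t convention: α weights the positive class and 1−α the
  negative, so the unweighted cross-entropy limit is (γ=0, α=1) for
  positives and (γ=0, α=0) for negatives.
* box regression — smooth-L1 (β = 1/9) on the standard center/log-size
  offsets, positives only.
* optimisation — Adam, batch 1, lr 2e-3 for the desk presets; all
  initialisation and shuffling flows from one seed, so loss traces are
  bit-reproducible.

Inference: sigmoid scores, score threshold (0.3 default), a 2000-candidate
pre-NMS cap, box decoding with log-size offsets clipped to ±4, clipping to
the image, then greedy NMS at IoU 0.5 (descending score, ties by insertion
order).

## Multiview count fusion

The count estimator separates *what pods look like* (learned by the
detector) from *how much pod evidence maps to a count* (learned by the
regressor):

* **FM** — the detector's full conv stack with weights and batch-norm
  statistics frozen. By default the final max pool is skipped (a 128-px
  input yields an 8×8 map); `include_final_pool=True` gives the fully
  pooled map (512 → 16×16). Features are extracted once per view and
  cached; the FM never enters the optimisation graph, which is what makes
  the freeze contract literally bit-exact.
* **fusion** — channel-wise concatenation of the per-view maps at matched
  spatial size. View order is fixed (north-side block first, then south)
  because concatenation is not permutation-invariant; a permutation of
  views permutes channel blocks correspondingly.
* **RM** — conv→pool→norm, conv→pool→norm, conv (no pool/norm), flatten,
  three fully connected layers to a scalar. ReLU activations throughout
  (unspecified in the architecture contract; chosen as the stack's
  default). Desk widths (64, 48, 32) conv / (64, 32, 1) FC; the library
  default is the larger (256, 128, 64)/(256, 64, 1).
* **training** — targets are scaled by the training maximum so the loss is
  O(1). MSE loss (MAE selectable), Adam. Two regularisation options are
  off by default but available: per-channel standardisation of the fused
  features with training-set statistics (stored with the model), and
  decoupled weight decay. The RM has more parameters than desk-scale
  training sets have plots and can memorise the cached features (train
  r ≈ 0.99 against held-out r ≈ 0.6 in one ablation); in the regimes the
  package ships, held-out accuracy is nonetheless governed by the quality
  of the frozen FM — a briefly-trained FM generalises better for counting
  than a detection-converged one — so the defaults favour the plain
  optimiser and a short detector pretraining. Predictions are clamped to
  ≥ 0 at the estimate layer.

A trained model has a fixed view arity; feeding a 1-view set to a 3-view
model is an error, never silent padding.

## Plot tracking

Detections are reduced to box centroids. Per frame, active tracks and
detections are matched greedily on the pairwise Euclidean distance matrix —
repeatedly take the global minimum, delete its row and column — with a
maximum-distance gate (half the frame width via
`CentroidTracker.for_frame_width`; ungated by default). Unmatched
detections open fresh, never-reused IDs; an unmatched track keeps its last
centroid as its anchor and retires after 5 consecutive misses; a match
resets the counter. Ties at equal distance resolve to the lower track
index, then the lower detection index (NumPy argmin order).

Greedy global matching is not the Hungarian optimum in adversarial
geometry, but in the pan-video regime it exists for — inter-frame
displacement (≈ pan speed) an order of magnitude below plot spacing — the
two coincide, and the oracle tests draw their instances from exactly that
regime.

## Evaluation

* **AP/mAP** — detections are matched to truths greedily in descending
  score order (each detection takes the unmatched truth of highest IoU
  ≥ 0.5); AP is the area under the precision envelope over recall
  (all-points interpolation, the modern convention); mAP averages classes.
  Undefined without ground truth: raised, not defaulted.
* **Count agreement** — Pearson r, MAE, and predicted/true std ratio. The
  std ratio documents the expected narrowing of predicted ranges when
  training data is mean-heavy; the test suite asserts ratio ≤ 1 on an
  imbalanced fixture rather than pretending the phenomenon away.
* **Selection ranking** — "positive" = plot selected (top-k by count).
  k = round-half-up(n·fraction) with explicit per-side overrides, because
  published tables can imply unequal effective k through ground-truth ties
  (e.g. k = 11 at 20% of 51 where rounding gives 10); ties at the cutoff
  are included wholesale, so the selected set may exceed nominal k.
  Metrics are rounded half-up to 2 decimals with exact decimal arithmetic
  (0.925 → 0.93 — a binary float round would get this wrong).
* **Seeds** — `pods_to_seeds` is the plain product with the ≈2.0–2.2
  seeds/pod multipliers of mature soybean.

## Synthetic scenes

The generator reproduces the *statistical* structure of breeding-plot
imagery, not its appearance: counts uniform in [pods_min, pods_max]
(default 100–1100), 1–10 plants (≈1 per 120 pods) as stem polylines, pods
as textured rotated ellipses in a brown/tan palette (60/40 genotype split)
with elongation 2–3.5 and uniform orientation. Pod areas are specified at a
`reference_width` (2048 px default, standing in for full-resolution
imagery; 30–4000 px² default range) and scaled by
`(image_width/reference_width)²` at render time with a 4-px² floor.

Views: each view renders the same pods with small parallax jitter
(σ ≈ 1.5 px), an independent exposure factor U(0.75, 1.25), and
independent foliage occlusion — with probability `occlusion_fraction` a
pod receives a green occluder ellipse whose overlap targets U(0.15, 0.95)
of its area. Side-2 views are mirrored. Visibility is measured exactly by
rasterised masks (pod pixels under the union of occluders), and a pod is
annotated in a view only when its visible fraction reaches the 0.25
threshold — a convention standing in for a human rater ignoring
nearly-hidden pods, since no published annotation rule exists; it is
configurable. Pod-on-pod overlap is incidental and does not count as
occlusion, which keeps the zero-occlusion invariant (every pod annotated in
every view) exact.

Backgrounds: *control* is a near-black backdrop (mean intensity < 40);
*in-field* is mid-tone clutter (random vegetation-coloured blobs) with
deliberately low contrast against the pod palette. Pan videos lay rendered
plots on a strip separated by 0.45 plot-widths of background and slide a
one-plot-wide window at `pan_speed` (default 12 px/frame, giving ≈30–40
frames per plot at 256 px, inside the observed 13–98 range).

One `numpy.random.default_rng(seed)` stream drives everything; identical
config + seed is bit-identical down to the PNG bytes.

**What the generator does not emulate** — and therefore what passing tests
do *not* show about real data: photorealistic pod/leaf appearance, lodging
and plant-architecture covariates, perspective and lens distortion, motion
blur, lighting gradients within a view, and annotation noise from human
raters. Results on these scenes demonstrate that the pipeline's machinery
is correct and that multiview fusion recovers counts under controlled
occlusion; they say nothing quantitative about field imagery.

## Desk-scale problem sizes

Chosen once as the package's working scale: 128×128 scene renders for
training (512×512 remains the generator default for visual inspection),
detector pretraining on 8 detection-friendly scenes (40–80 pods of
1500–6000 px² at reference 512) for 12 epochs, count regression on 60
training / 16 held-out plots with 3 regression seeds. At this scale the
whole acceptance run takes a few CPU-minutes. At 128 px the count signal
itself saturates with pod overlap — a perfect pod-pixel-coverage oracle
correlates r ≈ 0.73 (one view) / 0.87 (three views averaged) with the true
count at occlusion 0.5 — so held-out correlations of 0.8–0.9 for the
learned 3-view model sit close to the physical ceiling of the regime, the
run-to-run spread across detector seeds is substantial, and the 3-view
advantage over 1-view is the mechanism the fusion exists to demonstrate.

## Known limitations

* The NumPy networks are float64 and single-image-batch; they are meant for
  desk-scale experiments, not production GPU training.
* Greedy tracker matching can differ from the optimal assignment if plots
  move more than half their spacing between frames.
* The RM's fully connected head ties it to one FM spatial size; a model
  trained at 128 px expects 128-px inputs.
* VIA support covers rectangular regions only — polygons raise a
  descriptive error rather than being approximated.
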