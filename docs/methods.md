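# Methods

`camaudit` quantifies the quality of heatmap (saliency) explanations
attached to lesion-detection models in medical imaging. A "good" heatmap in
this setting is one that (1) barely changes when the input changes in
clinically irrelevant ways, (2) points at the place a reader would call the
evidence, and (3) actually reflects what the model computed rather than a
generic image property. These three properties — consistency, plausibility,
fidelity — are computable from data; a fourth, usefulness, requires a human
reader study and is carried through the report as a structured placeholder.
The criteria are evaluated in that fixed order: an explanation that is not
even stable under dose noise is not worth localizing, and one that does not
match ground truth still needs its mechanism checked before any human time
is spent on it.

## The phantom substrate

All quantitative checks run on synthetic mammography-like phantoms with
exact ground truth, so the evaluation never inherits annotation noise.

An image is

```
I = clip( B + A * L + photon noise , 0, 1 )
```

* **Background `B`** — sum of two mean-zero Gaussian random fields around a
  base level of 0.35: a slowly varying *tissue brightness* field (Gaussian
  correlation scale 24 px, sd 0.10) that produces bright regions which are
  not lesions, and a fine *parenchymal texture* whose correlation length
  `0.4 + 1.2 * (1 - density)` px shrinks as the density proxy grows
  (`density` in [0, 1], default 0.5). The two-scale construction matters:
  the bright large-scale blobs give intensity-driven explainers something
  misleading to highlight, while the fine texture determines how hard the
  matched-filtering task is.
* **Lesion `L`** — a radially symmetric Gaussian profile, sigma =
  radius / 2, peak amplitude `A = 0.32`, truncated to a
  `(2 * radius + 1)^2` support; default radius 8 px on a 128 px image.
  Exactly `round(n * lesion_fraction)` images carry one lesion
  (round-half-even), at uniform in-bounds positions; the half-open
  bounding box `(row_min, col_min, row_max, col_max)` is exact by
  construction. The study default is 150 images with fraction 0.5.
* **Photon noise** — pixels are treated as mean photon counts at gain
  G = 1000 counts per unit intensity and relative dose `d` (1.0 =
  reference): counts ~ Poisson(d G I) / (d G). The expectation is
  preserved and the noise variance scales as 1/d, so halving the dose
  doubles the noise power. Doses at or above 1e6 take a noise-free branch.
  This 1/d law is the package's modeling choice for "lower dose = noisier
  image"; no claim is made that it reproduces any particular scanner.
* **Rotation** — bilinear, about the image centre, out-of-frame pixels
  filled with the background mean (a constant fill at any other level
  creates a high-contrast frame that CAMs latch onto). Right angles on
  square images use an exact permutation. `inverse_rotate` maps a heatmap
  computed on a rotated image back to the original frame and returns a
  validity mask of pixels that survived the round trip; all consistency
  metrics are restricted to that mask. Measured round-trip mean absolute
  error at 50 degrees on these band-limited images is below 0.02.

What the phantoms do **not** emulate: breast anatomy, X-ray transport,
scatter, detector MTF, multi-lesion images, or realistic lesion margins. A
result on phantoms therefore demonstrates that the *evaluation machinery*
behaves as designed (oracle bounds are attained, orderings have the
predicted sign), not that any particular explainer is adequate on clinical
images.

## Reference detectors

The framework only assumes the `DetectionModel` contract: a presence score
in [0, 1] with a predicted box, per-layer C×H×W activations, and
non-mutating `with_randomized_layers` / `with_ablated_channel`
constructors. Two desk-scale models implement it.

**Template detector (white box).** Normalized cross-correlation (NCC) of
the image with the generator's own lesion profile; the score is a logistic
function of the maximum correlation (gain 25, midpoint 0.66 — the midpoint
sits between the measured distributions of background peak correlations and
lesion correlations, i.e. an equal-error placement). The predicted box is a
lesion-sized box centred on the correlation argmax: the model's entire
evidence is that peak, which is what makes the white-box fidelity check
possible. Its CAM layer stacks two Gaussian-smoothed copies of the input
with the correlation map; only the correlation channel feeds the score, so
channel ablation has a known truth. At the study conditions this detector's
AUC is ~1.0 at dose 1 (n = 150), degrading as dose falls.

**Small CNN.** A compact convolutional presence classifier: a fixed
first-layer filter bank (Gaussians at sigma 1–3 px and centre-surround
difference-of-Gaussian kernels at sigma 1.5–3.5, ratio 1.6, 15×15 support),
instance normalization, then two trained convolution layers (12 filters
5×5, 12 filters 3×3, each followed by ReLU and 2×2 mean pooling between
blocks) and a trained logistic readout on per-channel mean and max of the
last conv layer. The fixed multi-scale front end is a standard
scattering-style choice that keeps the trained part small; the mixing
layers and head are fit by full-batch Adam (lr 3e-3, default 60 epochs) on
the cross-entropy, with hand-written backpropagation in numpy — training is
bit-for-bit deterministic given the seed. Held-out AUC at the study
conditions is ~0.98–1.0. Layer randomization redraws the named layers from
the generic He-normal convolution initializer (for the head, standard
normal); with all layers randomized, accuracy drops to chance.

Instance normalization after the first layer is load-bearing: the low-pass
channels carry a large DC component (~0.35) that would otherwise swamp the
small band-pass responses in the mixing layers.

## Explainers

* **Eigen CAM** — first right singular vector of the raw (uncentered)
  channels × pixels activation matrix, reshaped to a map. The SVD sign is
  fixed by requiring a non-negative spatial mean. No model weights enter
  the computation, which is exactly why its fidelity is expected to be
  weak.
* **Ablation CAM** — channel weights `(y - y_c) / y`, where `y_c` is the
  score with channel `c` zeroed; the map is the positive part of the
  weighted channel sum. Weights are invariant to positive rescaling of the
  score. The "score" here is the lesion-presence score. Models may provide
  a `score_from_activations` fast path so the ablation loop does not
  recompute the full forward pass; its equality with the
  `with_ablated_channel` route is tested.
* Both maps are clamped at zero, bilinearly upsampled to input resolution,
  and min-max normalized; a constant raw map becomes all zeros and is
  flagged degenerate.
* Two reference explainers support calibration and controls: the
  ground-truth-indicator oracle (upper-bounds plausibility at exactly 1)
  and a constant explainer (must be flagged by every fidelity check).

## Metrics and the ROI rule

Heatmap pairs are compared by SSIM (window 7, data range 1), MSE, and an
IoU of the two maps binarized at their own top-10% quantile (scale-free;
the quantile is configurable). Two equal constant maps are defined to have
SSIM 1. Box IoU is plain pixel-set intersection over union on half-open
boxes.

The ROI of a heatmap is a fixed-size box centred on the *highest-activation
area*: a unique global maximum centres the box on itself; a tied plateau
centres it on the plateau centroid (half-up rounding). The plateau rule is
what makes the oracle explainer's plausibility exactly 1 — the indicator of
the truth box reproduces that box as its ROI — and the same centred-box
helper builds the detectors' predicted boxes, so a self-explaining
white-box model attains IoU 1 identically. A uniform map yields the centred
ROI. The default ROI size is the image's own ground-truth box size, so a
perfect explanation can attain IoU 1.

## Criteria

**Consistency** compares each image's heatmap against the heatmap of the
perturbed image, per perturbation level: dose factors {1.0, 0.66, 0.5,
0.33} and rotation angles {0, 10, 25, 50} degrees by default. Dose level
1.0 and angle 0 are identity levels and must give SSIM 1 / MSE 0 / IoU 1
exactly. Rotated heatmaps are realigned to the original frame and metrics
restricted to the validity mask. Model correctness is recorded at every
level, because the signature pattern — explanations drifting while accuracy
is flat — is only visible when both are reported. Aggregation is the mean
with a 2000-resample percentile-bootstrap 95% CI; a result where the
explainer is degenerate on more than half the images is flagged unreliable.

**Plausibility** is the mean box IoU between the heatmap ROI and the
ground-truth lesion box over lesion-present images; lesion-absent images
contribute only to the co-reported accuracy, and IoU and accuracy are never
blended into one scalar. Explainer comparisons on the same images use a
one-sided paired sign-flip permutation test (10 000 flips) on the
per-image IoU differences.

**Fidelity** has four checks:

* *Weight randomization* — re-initialize layers (independent per layer,
  cascading from the top, or jointly) and compare explanations before vs
  after, with a control arm that re-explains the unchanged model (must be
  exactly similar). Mean pre/post SSIM at or above 0.99 under a real
  randomization flags the explainer low-fidelity. Accuracy before and
  after is part of the record by construction: similarity change alone
  cannot distinguish a faithful explainer on a broken model from an
  unfaithful one on an intact model.
* *Masked-ROI (single) deletion* — replace the heatmap's ROI with the
  background mean, re-score and re-explain. The background-mean fill (not
  zeros) avoids injecting a high-contrast square that would itself drive
  the score. One caveat discovered during development: for a matched
  filter, masking the heatmap peak on a lesion-absent image still shifts
  the score, because the score is the global correlation maximum and the
  peak is wherever that maximum sits; off-peak masks are the ones that do
  nothing. The package therefore exposes a random-placement control
  (`random_mask_score_changes`) for calibrating what "no effect" looks
  like.
* *Incremental deletion* — repeatedly mask the next-highest (or
  next-lowest, or random) non-overlapping region of the original heatmap,
  re-scoring after each step; the curve's area is the mean of post-step
  scores, so it is invariant to the step count. Curves are compared on
  lesion-present images, where the importance ranking points at genuine
  evidence; on empty backgrounds all orders reduce to noise around the
  (low) baseline and the masking edge artifact can even raise a matched
  filter's score slightly. If no admissible non-overlapping box remains,
  the curve truncates with a flag.
* *White-box check* — on the template detector, whose true evidence region
  is its correlation peak, the explainer's ROI is compared by IoU against
  the detector's own predicted box. A self-explaining map scores 1
  exactly; a constant map scores the geometric chance overlap.

**Usefulness** is represented as a placeholder block (task, with/without
explanation arms, endpoints of task performance and time-to-decision) —
running a reader study is out of scope by design.

## Scorecard and gating

`run_framework` executes the three computable criteria in order and
assembles the two-part card (descriptive fields + quantitative reports +
usefulness placeholder). Gate metrics are fixed: mean SSIM over
perturbation levels (consistency), mean IoU over lesion images
(plausibility), and randomization sensitivity `1 - mean pre/post SSIM`
(fidelity). Thresholds are **user configuration with no defaults**:
acceptability depends on task and modality, so an unset threshold reports
metrics with status `not_evaluated`, and every criterion after a failed one
is reported with status `gated` — computed and shown, but without a
verdict. The gating is derived inside the framework; callers cannot emit a
"passed" downstream of a failure. Cards serialize to markdown or to JSON
validated by the pydantic model whose schema ships with the package.

## Problem sizes and numerical choices

The shipped study runs 150 images at 128×128 with radius-8 lesions; the
CNN trains on 100 images for 60 epochs (~40 s); deletion curves use 6
steps of 16×16 on 30 lesion images with 20 random-order seeds;
randomization checks use a balanced 30-image subset. Per-image seeds derive
from the dataset seed via `numpy` `SeedSequence` spawn keys, so generation
is reproducible and order-independent; every stochastic evaluation takes an
explicit seed and bootstrap/permutation resamplers are seeded. Constant
maps are special-cased in SSIM; degenerate (all-zero) heatmaps are flagged
rather than raised; box conventions are half-open and 0-based everywhere.

## Known limitations

* The phantom's 1/dose noise law and two-scale background are modeling
  choices; real dose-response and parenchymal texture are more complex.
* Ablation CAM inherits the presence score; for detectors with richer
  outputs (per-box class logits) the channel weights would need a choice
  of target.
* The accuracy component of fidelity conflates "explanation tracked the
  mechanism" with "perturbation degraded the model"; the control arm and
  the dual similarity+accuracy report mitigate but do not remove this.
* Plausibility uses the lesion box as the only ground-truth level;
  context-level ground truth (e.g. gaze data) is not modeled.
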