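# Methods

## Problem

Video laryngoscopy produces long recordings (≈20 s at 25 fps) in which the
overwhelming majority of consecutive frames are near-duplicates. `laryvid`
implements a two-stage pipeline: (1) *summarization* — reduce a video to
its structurally distinct keyframes by thresholding the Structural
Similarity Index (SSIM) between consecutive frames; (2) *classification* —
assign each keyframe to one of three vocal-fold conditions (healthy,
nodule, polyp) with a dual-backbone feature-fusion CNN under frozen or
fine-tune-last-k transfer regimes, evaluated with the standard multiclass
metric suite (precision/recall/F1, accuracy, MCC, one-vs-rest ROC/AUC,
k-fold cross-validation).

## SSIM

For two grayscale images x, y the per-window score is

    SSIM(x, y) = (2 μx μy + C1)(2 σxy + C2) /
                 ((μx² + μy² + C1)(σx² + σy² + C2))

with C1 = (K1·L)², C2 = (K2·L)². Defaults follow the de facto reference
configuration: K1 = 0.01, K2 = 0.03, L = 255, 11×11 Gaussian window with
σ = 1.5. Choices a caller can change through `SSIMParams`:

- **Window**: `gaussian` (default) or `uniform`; any odd size ≥ 3. A
  `global` mode treats the whole image as one uniform window (useful for
  tiny test images).
- **Moments** are weighted population moments (no Bessel correction),
  matching the reference formulation.
- **Boundaries**: valid-window convention — no padding; the SSIM map is
  smaller than the image by `window_size − 1` per axis. Padding would
  manufacture artificial similarity at the borders.
- **Color**: SSIM is computed on grayscale; RGB input is converted with
  BT.601 luma weights (0.299, 0.587, 0.114).

The formula is bounded by [−1, 1] and can genuinely be negative for
anti-correlated structure (e.g. two independent noise images); no clamping
is applied. Identity gives exactly 1, and for positively correlated pairs
the score is positive. The implementation computes local moments with
separable correlation; tests verify agreement (≤1e−7) with a brute-force
per-window enumeration oracle and with scikit-image's implementation under
matching settings.

## Keyframe selection

Given a video, the consecutive-SSIM trace has N−1 entries; frame i (i ≥ 1)
is a keyframe iff `trace[i−1] < threshold` (strict: a score exactly at the
threshold is not "below" it). Frame 0 is always a keyframe — without this
seed a constant video would produce an empty summary. Each frame is
compared to the immediately preceding *raw* frame; an optional
compare-to-last-keyframe mode accumulates drift against the last selected
anchor instead (different semantics, off by default). Thresholds are
fractions in (0, 1); the default sweep is {0.90, 0.95, 0.98}. Selections
are nested across thresholds (t1 ≤ t2 ⇒ keyframes(t1) ⊆ keyframes(t2)), so
per-threshold counts are monotone non-decreasing — the qualitative pattern
a per-threshold count table should show. Reported reduction fraction is
exactly 1 − kept/total.

## Synthetic data

Real laryngoscopy recordings are private, so the generator targets the
*statistical contract* the pipeline consumes, not photorealism:

- **Scene**: radial illumination gradient (level ~U(165, 215), falloff
  ~U(90, 130)) plus a band-limited Gaussian texture field (std 10 gray
  levels) plus the class lesion.
- **Lesions** follow clinical morphology: healthy = none; nodule = two
  small symmetric blobs (σ ≈ 0.05·min(H,W)) mirrored about the midline;
  polyp = one larger unilateral blob (σ ≈ 0.11·min(H,W)). Blob amplitude
  ("contrast") defaults to 80; positions are randomized within margins that
  keep lesions inside the frame. `contrast = 0` removes all lesions,
  producing a chance-level control.
- **Temporal model**: per-frame sub-pixel translation random walk (default
  step std 0.05 px), multiplicative flicker, additive Gaussian sensor noise
  (default std 0.5). At each *event* index the scene is rebuilt — fresh
  texture, illumination center displaced by a radius drawn from
  [0.6, 1.0]·event_magnitude (default 16 px), lesion repositioned — standing
  in for camera jumps and new clinical content.

Defaults were calibrated once and frozen; the test suite re-asserts the
resulting contracts empirically rather than trusting the constants:
non-event transitions score SSIM > 0.98 and event transitions < 0.90
(checked over ≥20 seeded videos), and a linear classifier on 8×8
mean-pooled patches separates the three classes with > 0.9 held-out
accuracy at default contrast. Everything is bit-identical given the seed.

What the generator does **not** emulate: anatomy, specular highlights,
gag-reflex motion blur, interlacing, compression artifacts, or gradual
scene transitions. Passing tests therefore demonstrate the pipeline's
mechanics (threshold semantics, bookkeeping, learnability of a separable
signal), not clinical performance on real tissue.

## Classifier

Two convolutional backbones process the same input; each is reduced to a
feature vector by global average pooling; the vectors are concatenated
(fused width = sum of branch widths) and passed to a dense head (one
hidden layer of 256 by default, dropout 0.3) ending in a softmax over 3
classes. Regimes:

- `frozen`: every backbone layer non-trainable; only the head learns. A
  frozen batch-norm layer runs in inference mode and never updates its
  running statistics, so a frozen backbone is bit-inert through training.
- `fine_tune_last_k`: exactly the last k entries (default 20) of each
  backbone's flat layer list are unfrozen, plus the head. "Layer" means
  one entry of the layer list — convolution, batch-norm, activation and
  pooling entries all count — and the count is recorded on the built model
  so the convention is auditable.

The built-in `tiny` backbone is a 22-entry stack (conv-ReLU stem, then
five conv → batch-norm → ReLU → max-pool blocks, widths 16/24/32/48/64,
~53k parameters) that trains in seconds on one CPU with no downloaded
weights. Other architectures plug in through `register_backbone`; no
pretrained builder ships with the package.

Training is Adam (lr 0.001), batch size 32, ≤30 epochs, early stopping on
validation loss with patience 5 and best-weight restore — a fixed
hyperparameter set so that compared runs differ only in the variable under
study. The whole stack (conv via im2col, batch-norm, pooling, dropout,
Adam) is implemented in numpy inside `laryvid.nn`; gradients are verified
against finite differences in the tests. Batch-norm running statistics are
seeded from the first training batch: with only a handful of batches per
epoch at desk scale, the conventional (0, 1) cold start leaves validation
metrics meaningless for several epochs and falsely triggers early
stopping.

Inputs are grayscale (or RGB) images scaled to [−1, 1]; both branches
share one input tensor. The default input side is 32 (the tiny backbone
needs multiples of 32); there is no claim that this matches any particular
pretrained architecture's native size.

## Data handling

Keyframes are exported as lossless PNG (`<video_id>_f<index:06d>.png`) with
a CSV manifest (file path, video/patient id, class, frame index, split).
Directory readers use strict lexicographic order of zero-padded names.
Resizing is bilinear with output pixel centers mapped linearly onto input
pixel centers and edge clamping (`scipy.ndimage.map_coordinates`, order 1)
— a fully specified rule that tests verify against hand-computed values.
Video-file decoding is attempted through imageio and requires a
codec-capable plugin; PNG/JPEG frame directories are the primary input
form and are what the generator emits.

The default train/validation split is frame-level, stratified by class:
within each class, round(n·val_fraction) records go to validation
(per-stratum counts within one record of the requested 80/20 ratio),
deterministic given the seed. Because a frame-level split can place frames
of the same patient on both sides — a genuine leakage concern — a grouped
mode assigns whole patients to one side; it is provided as an option, not
the default.

## Metrics

All metrics derive from the confusion matrix (rows = true, columns =
predicted) by one-vs-rest reduction: precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = harmonic mean, accuracy = trace/total, macro averages are
unweighted means. MCC uses the multiclass generalization
(s·c − p·t)/√((s²−p·p)(s²−t·t)), which reduces exactly to the binary
closed form for 2×2 matrices; the result is clipped to [−1, 1] to absorb
sqrt round-off. Zero denominators yield 0 with a warning. AUC is the
one-vs-rest midrank Mann–Whitney statistic; classes absent from the truth
get NaN. Cross-validation uses stratified k-fold (default k = 5,
seed-deterministic) and aggregates per-fold metrics as mean ± sample
standard deviation (ddof = 1). Reports store values on the 0–1 scale and
can render 0–100.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale on one CPU:
videos of 30–50 frames at 64×64, cohorts of 9–18 videos, classification
sets of 100–300 images at 32×32, and training runs of ≤30 epochs
(~1–2 minutes for the full acceptance script). Chance-level controls are
measured on a held-out test split rather than the early-stopping
validation split, because best-epoch selection on the validation set
biases a chance measurement upward. Floating tolerances: SSIM identity
1e−9, oracle agreement 1e−7, metric oracles 1e−12. Argmax prediction ties
resolve to the lowest class index.

## Known limitations

- Pretrained ImageNet backbones (and therefore any headline accuracy on
  real clinical data) are out of scope; the harness proves the transfer
  contracts on the built-in tiny backbone.
- The SSIM threshold is global and fixed per run; adaptive per-patient
  thresholds are not implemented.
- Synthetic events are abrupt; slow dissolves between scenes would produce
  intermediate SSIM values for which the single-threshold rule has no
  special handling.
- `cross_validate` re-trains per fold from scratch; at k = 5 with the tiny
  backbone this is minutes, with a real backbone it would not be.
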