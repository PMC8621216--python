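# Methods

## Problem and approach

Lung ultrasound (LUS) distinguishes normally aerated parenchyma —
marked by **A lines**, horizontal reverberation artifacts of the
pleural line repeating at integer multiples of the pleural depth —
from alveolar-interstitial syndrome, marked by **B lines**, bright
vertical rays running from the pleural line to the far field. The
package implements a two-part pipeline for this binary call:

1. a **frame-level classifier** mapping one masked grayscale frame to
   a probability pair `p = [pA, pB]`, and
2. a **clip-level decision rule** that aggregates the ordered
   frame-wise B-line probabilities `PB = {pB1, …, pBn}` of a clip:

   ```
   ŷ = 1[ ∨_{i=1}^{n−τ+1} ( ∧_{j=i}^{i+τ−1} pBj ≥ t ) ]
   ```

   with classification threshold `t ∈ [0.5, 1)` and contiguity
   threshold `τ ≥ 1`. A clip is called B-positive iff some window of
   exactly τ consecutive frames all reach probability `t`.

The rule exists because many pathological clips are *heterogeneous*:
B lines slide in and out of view with tidal respiration, so most
frames show A lines. Averaging `PB` over the clip dilutes the short
B runs below any sensible threshold and produces a falsely negative
"normal" call; requiring a short contiguous run catches these clips,
while isolated single-frame false positives are defeated by `τ > 1`.

Decisions baked into the rule:

- the comparison is inclusive (`pB ≥ t`), so boundary ties count as
  B frames;
- a clip shorter than τ is called A — the disjunction over window
  starts is empty;
- the reported triggering window is the earliest one;
- the averaging baseline is mean-probability thresholding,
  `ŷ = 1[ mean(PB) ≥ θ ]` with θ = 0.5.

The (t, τ) surface is explored over the grid t ∈ {0.5, 0.6, 0.7,
0.8, 0.9}, τ ∈ {1 … 40}; the operating point maximizes
sensitivity + specificity, ties broken toward smaller τ then smaller
t (a simpler rule is preferred at equal performance). Both grids are
configurable. Per-clip decisions are monotone in both thresholds, so
dataset sensitivity is non-increasing and specificity non-decreasing
along either axis; the tests assert this numerically.

## Frame classifier

The network is the first three convolutional blocks of a VGG16-style
architecture: (2, 2, 3) convolution layers of (64, 128, 256) 3×3
single-stride, spatially padded filters with rectified-linear
activations, 2×2 max-pooling after blocks 1 and 2 only (the third
block's pool is removed, so the downsampling factor is exactly 4),
then global average pooling → dropout → a 2-node dense layer with
softmax. Parameter total: 1,734,850 for single-channel input.

No deep-learning framework is used: the layers, their backward
passes, and an Adam optimizer are implemented directly on numpy,
with convolutions lowered to BLAS GEMMs against shifted views of the
padded input. This keeps the package dependency-light and the
arithmetic single-threaded and reproducible; it is not a
general-purpose autograd, only the fixed architecture above.

Training choices (hyperparameters with defaults):

- optimizer Adam, learning rate 1e-4 (`TrainConfig`); the packaged
  end-to-end experiment uses 1e-3 because its training sets are small
  and the phantom task is easy, so larger steps converge within a few
  epochs;
- dropout 0.5; batch size 8; early stopping on validation loss with
  patience 3, best-validation weights restored;
- inverse-frequency class weighting in the cross-entropy (on by
  default) to absorb A/B imbalance;
- stochastic augmentation applied to training batches only, with the
  beam mask re-applied after the geometric transforms so
  out-of-sector pixels stay zero;
- initialization is He-scaled random. A `pretrained_init` flag exists
  for ImageNet-style warm starts but is off by default and
  unimplemented here, keeping runs self-contained and deterministic.

Frames are classified independently; predictions are pure functions
of pixels, so permuting frames permutes predictions (asserted as a
property test).

## Preprocessing

Real LUS frames carry vendor screen furniture outside the beam. The
masking step zeroes everything outside a configurable sector polygon
(JSON-serializable); it is idempotent and rejects size mismatches.
Synthetic frames are born masked, so this op mainly serves real-data
compatibility and contract testing. The polygon must be simple and
cover more than 20% of the image; degenerate (near-empty) masks are
rejected rather than silently producing blank frames.

Augmentation draws per frame: rotation ±45°, translation ±10% of
each dimension, zoom ±10%, one-sided counterclockwise shear up to
10°, fair-coin horizontal flip, multiplicative brightness ±30%
(a +30% draw maps mid-gray 0.5 to 0.65). Geometric terms are composed
in a fixed order (rotate → shift → zoom → shear) and applied in one
bilinear warp with zero fill; intensities are clipped to [0, 1]. The
shear is one-sided because the stated range is directional; the
brightness change is multiplicative, the standard convention.

## Data splitting

All clips of a patient are confined to one of train/validation/test
in every fold. Fold assignment is stratified by the patient's
majority clip label (patients are dealt round-robin within class), so
both classes appear in every test fold even at small n; this requires
at least k patients per class. The validation fraction defaults to
10% of patients per class. Separately, clips are routed into two
disjoint pools: homogeneous clips available at frame-training time
(batch marker ≤ cutoff) feed frame training; heterogeneous clips and
later-labelled homogeneous clips are reserved for clip-level
inference. The pools share no clip id, and the driver asserts this.

## Synthetic phantom

The generator emulates sector-scan (phased-array) LUS frames with
only the features the classifier needs:

- a fan-shaped field of view from a virtual apex above the image
  (sector angle 70° by default), pixels outside exactly 0;
- a bright pleural band at 25% of image height (Gaussian radial
  profile, σ ≈ 1.6 px);
- A frames: up to 3 reverberation arcs at integer multiples of the
  pleural depth with geometrically fading amplitude;
- B frames: 1–9 bright rays from the pleural line to the far field at
  fixed angles per clip, FWHM 6 px at the pleural line (128×128);
- multiplicative Gaussian speckle (σ = 0.08) and a global brightness
  jitter (±10%) per frame.

Severity follows the clinical grading: *mild* = fewer than 3 rays,
*moderate* = rays covering < 50% of the pleural-line extent,
*severe* = > 50%; the generator chooses ray counts that realize the
requested grade under the configured geometry and errors out when the
geometry cannot realize it (narrow rays are needed at small image
sizes). Heterogeneous B clips derive per-frame labels from a
sinusoidal respiration phase (period 20 frames, visibility threshold
0.45, giving B-present fractions near one third and contiguous runs
of several frames); ray opacity follows a half-sine over each run so
B lines fade in and out of view. Default clip length is 30–60 frames.
Cohorts assign each patient one dominant pattern (B with probability
`class_mix`), 2–4 clips per patient, a heterogeneous fraction among B
clips (default 0.4), and a late-labelling batch flag on 15% of
homogeneous clips so pool routing is exercised.

What the phantom does **not** model: acoustic physics, probe and
vendor variability, curved-linear/linear geometries, pleural
irregularity, consolidations, rib shadows, or patient-level
covariates. The phantom is separable by a hand-written angular-energy
oracle at ≥ 99% frame accuracy, and that is the point: passing tests
demonstrate that the pipeline's machinery (training, routing,
aggregation, thresholds, attribution) is correct, not that the
classifier would reach any particular performance on hospital data.

## Explainability

Grad-CAM targets the final convolutional maps of block 3 (deepest
spatial layer, 1/4 resolution). With a global-average-pooling head
the gradient of the class logit with respect to map k is spatially
constant, so the channel weight reduces to the dense-layer weight
over the map area; the heatmap is the rectified weighted sum,
bilinearly upsampled and max-normalized. The default overlay (`convention="paper"`) uses the
inverted colour convention some clinical figures prefer — blue =
highest importance, red = lowest; standard jet (red = high) is
available via `convention="standard"`.
On trained models the tests require the heatmap mass on known ray
pixels to exceed the off-ray mass on correctly classified B frames
(sign test, p < 0.05).

## End-to-end experiment sizes

The packaged experiment (`ExperimentConfig` defaults, also run by
`scripts/acceptance.py`) generates 40 patients × 2 clips of 24–32
frames at 128×128, uses 2 folds, trains ≤ 5 epochs at learning rate
1e-3 on 3 frames per training clip, evaluates frame metrics on 5
frames per held-out clip, and sweeps τ ∈ {1 … 12} (clips are ≥ 24
frames, and the informative τ range at these run lengths is small).
These sizes were chosen so the whole experiment runs on one CPU core
in minutes while keeping every stage statistically meaningful:
frame AUC is expected near ceiling because the phantom is separable
by construction. Augmentation is off in this run: its training and
test frames are i.i.d. draws from the same generative model, so there
is no domain gap for augmentation to bridge, and it is exercised by
its own tests instead.

## Numerical and degenerate-input conventions

- All image arithmetic in float32; probabilities reported in float64.
  Two runs with the same seeds are bit-identical on the same BLAS.
- Probability pairs must sum to 1 within 1e-6; F1 equals the harmonic
  mean of precision and recall within 1e-9 where both are defined;
  precision/recall/specificity are NaN when their denominator is 0.
- ROC/AUC uses scikit-learn's trapezoidal curve; tests pin it to
  brute-force Mann-Whitney pair counting (ties = ½) to 1e-12.
- Fold aggregation uses the sample (n−1) standard deviation.
- Empty clips, single-class pools/label sets, mismatched shapes, and
  inconsistent clip specifications are rejected with diagnostics
  rather than coerced.

## Known limitations

- The numpy training loop is single-core and unsuited to real
  datasets beyond desk scale.
- The phantom's simplicity means performance numbers here say nothing
  about clinical accuracy; they are correctness ceilings.
- The averaging baseline is the canonical mean-threshold reading;
  other pooling variants (median, top-k) are not implemented.
- Pretrained initialization and video-container ingestion are stubs
  by design (PNG frame directories and CSV manifests are the
  interchange formats).
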