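# Methods

This note records the modelling choices behind `kidneyfusion`: what is
computed, which constants matter and why they hold their defaults, what the
synthetic data generator does and does not emulate, and where the design
was genuinely open.

## Frozen-backbone fusion

The classifier family under study keeps one or two ImageNet-style backbones
completely frozen, concatenates their feature vectors (extractor A first),
and trains a single linear layer with bias on top.  Freezing makes the
parameter accounting exact and the optimization convex in the head: for
softmax cross-entropy with probabilities `p` and one-hot labels `y`, the
head gradients are `dW = (p − y)ᵀ F / B` and `db = mean(p − y)`, so no
automatic differentiation is needed anywhere.  All layers are therefore
implemented forward-only in NumPy (`kidneyfusion.nn`), and the package
never requires a deep-learning framework or a weight download.

### Truncation policies and parameter audits

Feature extractors are standard classification networks with trailing
layers removed.  The exact policy matters because the package's audits are
asserted to the parameter: AlexNet loses only its last 4096→1000 linear
(keeping both 4096-wide hidden linears, 57,003,840 backbone parameters);
ViT-B/16 loses its 768→1000 head and emits the class token after the final
layer norm (85,798,656); ConvNeXt-Large has two policies — `keep_norm`
(196,230,336; used alone) retains the pre-head 1536-wide layer norm, and
`drop_norm` (196,227,264; used inside fusions) removes it.  These are the
unique assignments under which every audited single and fused total is
internally consistent.  Swin-B is registered (1024-wide features, standard
window attention with relative position bias) but its reference total is
not asserted: the structural count of a standard Swin-Base trunk is
86,743,224, and no consistent assignment reproduces the published Swin
rows, so they are reported as informational only.

Counts depend only on layer shapes; `count_parameters` sums the element
count of every weight and bias array and is cross-checked in the tests by
an independent attribute-walking oracle.

### The tiny stand-in backbones

`tiny_a` (32 features) and `tiny_b` (48) replace the large backbones in
desk-scale runs.  Their filters are *fixed and handcrafted*, playing the
role that pretraining plays for the large networks — a frozen extractor is
only useful if its features already encode something:

* **conv1** (3×3, stride 2; 8 resp. 12 channels): each channel computes a
  3×3 box blur of the standardized intensity and thresholds it,
  `ReLU(z̄ − t_k)`, with thresholds evenly spaced on [−1.5, 2.3] — a ladder
  of survival functions of the local intensity distribution.
* **conv2** (3×3, stride 2; 16 resp. 24 channels): per band, (a) a
  *band-pass* `ReLU(z̄ − t_k) − ReLU(z̄ − t_{k+1})`, bounded by the
  threshold spacing so every channel reaches the head at a comparable
  scale; (b) a *Laplacian edge-energy* channel with a −0.2 bias so that
  pixel noise never reaches the pooled statistics; and (c) one
  *mid-intensity-mass* channel (3×3 average of a low ladder channel with a
  −5× brighter-channel exclusion, bias −0.3) that responds to contiguous
  regions that are neither background-dark nor organ-bright — thin
  bright-to-dark transition rings average out, solid mid-intensity
  interiors do not.
* **features**: global average (×16 gain, so area statistics and peak
  statistics arrive on comparable scales) and global max of every map.

Layer sizes: tiny_a 224 + 1,168 = 1,392 parameters, tiny_b 336 + 2,616 =
2,952.  The nets are input-size agnostic (global pooling); the large
backbones require 224×224 crops.

## The optimizer

Standard Adam keeps exponential moving averages `m` (gradient) and `v`
(squared gradient), bias-corrects them, and steps
`θ ← θ − α·m̂/(√v̂ + ε)`.  The norm-scaled variant computes the Euclidean
norm `n = ‖g‖` per parameter tensor and uses

```
θ ← θ − α/(n + ε) · m̂/(√v̂ + ε)
```

Two readings of the custom update exist because the printed update rule
places `m̂` in the denominator and `√v̂` in the numerator — inverted
relative to standard Adam and singular as `m̂ → 0`.  The package treats the
*intent* (scale the step by the gradient norm) as the default
(`norm_scaled`) and keeps the printed form as `literal`, flooring `|m̂|` at
`m_hat_floor = 1e-12` with sign preserved.  Which form was actually run by
the method's originators is not recoverable; both are first-class and both
are oracle-tested.

Further conventions:

* Norm scope is the *parameter tensor*, never the whole gradient vector;
  `step_all` dispatches tensor by tensor and skips absent gradients (this
  is how frozen backbones are expressed to the optimizer).
* Bias correction is retained in all variants; `β₁ = 0.9`, `β₂ = 0.999`,
  `ε = 1e-8` by default; no weight decay, no AMSGrad, no schedules.
* A zero gradient (`n = 0`) advances the moments and the step counter but
  leaves `θ` unchanged in both custom variants: the norm-based scale is a
  0/0 there, and the only self-consistent limit is "no step".  Standard
  Adam needs no guard (a fresh state yields `m̂ = 0`; with accumulated
  momentum it moves, as standard Adam does).
* The same `ε` is used in `(n + ε)` and `(√v̂ + ε)`.

### Stability at desk scale

A constant-rate Adam-family update never settles: once the training set is
nearly fit, `m̂/√v̂` stays O(1) for persistently-signed residual gradients
and the iterate jitters by ~α per coordinate per step.  The norm-scaled
variant adds a second effect: tensors whose gradient norm collapses (e.g.
an almost-fit bias vector, or a small all-correct batch) receive *amplified*
steps `α/n`.  At full scale (tens of thousands of steps, noisy batches)
these effects average out; at desk scale (~1,100 steps) they dominate
final-epoch accuracy.  The desk benchmark therefore uses heavier moment
averaging (`β₁ = 0.98`, `β₂ = 0.9999`) and a larger stability constant
(`ε = 1e-2`), which damp both effects without altering the update rule;
they are exposed as ordinary `TrainConfig` fields.

## Data pipeline

Datasets are folder-per-class trees of 8-bit JPEG/PNG images; classes are
always ordered alphabetically (Cyst, Normal, Stone, Tumor) in manifests,
label indices, confusion matrices, and reports.

* **Split.**  The default training fraction is 9725/12446 ≈ 0.7814, the
  study's proportion, which is not a round number; stratified allocation
  uses largest-remainder rounding (floor each class quota, distribute the
  leftover by descending fractional remainder, ties broken by class order)
  so the totals are exact.  On the full composition this yields exactly
  9,725 / 2,721.
* **Augmentation** (training mode): random horizontal and vertical flips
  (p = 0.5 each), color jitter (brightness/contrast/saturation 0.1, hue
  0.02, applied in that fixed order), resize to 256×256, center crop to
  224×224, ImageNet standardization (mean 0.485/0.456/0.406, std
  0.229/0.224/0.225), random erasing with p = 0.1.  Evaluation mode applies
  only resize → crop → normalize.  Jitter strengths and the fixed order are
  package choices; the flip and erasing probabilities and the geometry are
  the method's stated stack.
* **Doubling.**  "Augmentation doubled the dataset" is realized logically:
  a loader with `duplication=k` exposes `k·n` indices, each passing
  independently through the stochastic transforms; nothing is copied on
  disk.  With k = 2 the training/validation sizes become 19,450 and 5,442.
  Whether validation metrics should be computed on the duplicated
  (augmented) or unique validation set is ambiguous; the CLI emits both
  (`metrics.csv` on the unique set, `metrics_duplicated.csv` on the
  duplicated stream).
* **Determinism.**  Every stochastic transform derives its generator from
  `(seed, epoch, logical index)`, so runs are bit-reproducible on a single
  worker.

## Synthetic generator

The generator emulates the *layout and separability* of a four-class
abdominal CT dataset, not its anatomy.  Each grayscale image is a noisy
dark background with a bright bean-shaped "kidney" (ellipse with a hilum
notch; position, scale, and rotation jittered per image):

* **Normal** — bean only;
* **Cyst** — dark circular inclusion (intensity ≈ 38) with a sharp bright
  rim painted after smoothing;
* **Stone** — small saturated speck (255), also post-smoothing, so it stays
  crisp;
* **Tumor** — irregular mid-intensity blob (≈ 95, four-harmonic radial
  wobble) centred on the bean boundary so it crosses it.

Defaults: the study's class composition (3,709 / 5,077 / 1,377 / 2,283 =
12,446 images), 128 px, background noise σ = 8.  Images are written as
deterministic PNGs (byte-identical under a fixed seed).

What passing tests on these images shows: the pipeline, optimizer, and
evaluation machinery work end-to-end, and the architecture can separate
classes whose defining features are intensity distributions and simple
morphology.  What it does not show: performance on clinical CT, where
contrast differences are subtler, lesions vary enormously, slices carry
surrounding anatomy, and label noise exists.  No claim about real-data
accuracy is made or implied.

## Desk-scale benchmark

`kidneyfusion.benchmark.run_desk_benchmark` is the package's reference
end-to-end run: 400 synthetic images (100 per class) at 96 px, stratified
75/25 split, the full augmentation stack with ×2 training duplication,
tiny_a + tiny_b fusion (80-wide head), 30 epochs of `custom_adam` at
lr 3e-3, batch 16, `β₁ 0.98 / β₂ 0.9999 / ε 1e-2`.  These sizes keep the
run around a minute on one CPU while leaving the task non-trivial (the
96 px stone speck is 3–5 px across).  The learning rate is three orders of
magnitude above the full-scale default because a linear probe must cover
the same weight distance in a thousandth of the steps.  The run also
audits the freeze contract: every backbone array must be bit-identical
before and after training.

## Numerical choices, degenerate inputs, tie-breaks

* Optimizer state and updates are float64; model weights float32.
* Metric cells with a 0/0 ratio (e.g. precision of a never-predicted
  class) are reported as 0.0, collected in `zero_division_flags`, and
  surfaced once as a `RuntimeWarning` — reports stay machine-readable.
* Argmax ties break toward the lowest class index (NumPy convention),
  making evaluation deterministic.
* Grayscale images are replicated to three channels; corrupt files raise
  with the offending path; non-finite gradients or images are rejected by
  name.
* `ConfusionMatrix` rows are true classes, columns predictions.

## Known limitations

* Forward passes of the large backbones are NumPy-speed: fine for audits
  and shape checks (seconds), not for training campaigns at 224 px.
* Swin-B's published parameter totals cannot be reconciled with any
  standard Swin variant; its audit is informational.
* The `literal` optimizer variant is numerically fragile by construction;
  it is provided for fidelity and tested against the oracle, not
  recommended for use.
* The synthetic classes are easier than clinical CT by design; accuracy
  numbers from the desk benchmark characterize the pipeline, not the
  clinical problem.
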