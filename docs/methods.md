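# Methods

This note documents the models, numerical choices and limitations behind
`bcgnet`: a pipeline for hypertension (HPT) screening from single-channel
ballistocardiogram (BCG) signals, built around a multi-scale residual 1D
CNN with channel-attention fusion, 1D Grad-CAM explanations, and a
J-peak-neighborhood data-augmentation scheme, all exercised end-to-end on
a synthetic cohort generator with analytic ground truth.

## Signal model and preprocessing

A recording is a single-channel amplitude series at 100 Hz. Recordings
are cut into consecutive, non-overlapping 10 s windows (1000 samples)
anchored at sample 0; the trailing remainder is discarded. Each window is
z-scored using the population (1/N) standard deviation. The population
convention makes normalization exactly idempotent and gives the exact
mean-0/sd-1 postcondition that downstream thresholds (peak prominence in
z-units, heat-map significance at 0.5) rely on; sample-variance z-scoring
would differ by `sqrt(N/(N-1))`, immaterial at N = 1000 but not exactly
idempotent. Zero-variance windows raise an error instead of silently
returning zeros: a flat BCG window is a sensor fault, not a valid input.

## The synthetic cohort generator

Real overnight BCG corpora are large and access-controlled, so the
package bundles a seeded generator that emulates the statistical
structure the pipeline assumes, with analytic ground truth.

**Beat model.** One heartbeat is a sum of eight Gaussian bumps, one per
labelled deflection of the BCG complex (G, H, I, J, K, L, M, N), with
fixed offsets spanning ~0.65 s and amplitudes chosen so the J wave is the
dominant positive deflection (amplitude 1.0 z-units against 0.45 for H,
0.25 for L) and the systolic trough structure (I, K negative) matches the
canonical morphology. The exact offsets and widths are an artifact
choice; only the ordering G..N and J-dominance are treated as
constraints.

**Rate structure.** Per-subject mean heart rate is drawn from the
class-conditional distributions of the clinical cohort this pipeline
targets: hypertensive 77.10 ± 9.20 bpm, control 73.60 ± 8.30 bpm
(between-subject sd), clipped to [40, 180] bpm. Within a recording,
inter-beat intervals are drawn per beat from a normal distribution around
60/HR with an sd derived from a beat-to-beat heart-rate variability of
3 bpm (default), truncated to [0.33 s, 1.5 s]. Baseline drift is a
respiration sinusoid (0.25 Hz, 0.3 z-units by default) with random
phase; additive noise is white Gaussian (sd 0.1 z-units by default).
These levels are plausible for a quiet overnight mattress sensor; all are
configurable.

**Class morphology knob.** Rate alone separates the two classes only
weakly at desk scale (the class means differ by ~0.4 between-subject
sds), so the generator adds an explicit morphological contrast:
`morphology_shift` in [0, 1] deepens the K wave by a factor `1 + 0.4·s`
and compresses the systolic (G–K) offsets by `1 − 0.08·s`. The default
cohort uses shift 1 for hypertensive and 0 for control subjects. This is
a *simulator construct*, not a claim about real hypertensive BCG
morphology (which is far subtler); it exists so that end-to-end learning
tests are well-posed, and it deliberately confines class evidence to the
beat complex so that saliency localization can be tested. Setting the
knob to 0 yields a rate-only (hard) cohort.

**Ground truth and seeding.** The true J-peak index of each beat is the
local argmax of the noise-free beat train within ±5 samples of the
nominal J offset (discrete sampling can shift the continuous peak by one
sample). Seeding is hierarchical: subject i of a cohort with master seed
m uses `SeedSequence([m, i])` for its parameters and
`SeedSequence([m, i, 1])` for its signal, so cohorts are bit-reproducible
and subjects are independent. Full seed sequences (not truncated
integers) are used; truncation to 32 bits measurably degraded the
first-draw statistics of large cohorts.

**What the generator does not model:** hemodynamics, blood-pressure
coupling, motion artifacts, posture changes, sensor nonlinearity,
multi-night drift, or inter-subject morphology variability beyond the
rate draw and the class knob. Tests passing on this generator therefore
demonstrate the correctness and trainability of the pipeline, not
clinical performance.

## J-peak detection and augmentation

The detector makes "compare neighboring values in a local range"
precise: a sample is a J-peak iff it (a) is the strict maximum over
±0.3 s, (b) exceeds 0.5 z-units, and (c) lies ≥ 0.4 s (≈150 bpm ceiling)
from any higher accepted peak, accepted greedily by descending
amplitude. Plateau ties resolve to the leftmost sample. The bounds are
physiological: 0.3 s is below the minimum credible inter-beat interval,
and 0.5 z-units separates J from the secondary H/L deflections after
z-scoring. Detection quality is reported as corpus-level precision/recall
with one-to-one greedy matching at a ±3-sample tolerance; beats whose
true J falls just across a window boundary leave an L-wave bump that can
be flagged inside the window, which is why corpus-level pooling (the
standard for beat detectors) is used rather than a per-window minimum.

Augmentation replaces each segment by the concatenation of windows of
radius 15 (31 samples) around its detected J-peaks, in time order. A
fixed model-input length is obtained by padding with zeros, or truncating,
to 12 beats (12 × 31 = 372 samples): 12 beats covers rates up to 72 bpm
exactly in a 10 s window and truncates faster hearts. A segment with no
detected peaks yields all-padding with a warning flag — downstream code
decides whether to drop it. Boundary-crossing windows are dropped rather
than reflected or padded, to avoid fabricating signal. The augmented
data-set *replaces* the original segments rather than being appended to
them. Jittering (additive Gaussian noise), scaling (one multiplicative
draw) and time-warping (piecewise-linear monotone time remap from
Gaussian-perturbed anchors, with up to 10 retries on a non-monotone draw)
are provided as the traditional augmentation baselines.

## Network architecture

The classifier is a pre-activation residual 1D CNN:

* stem: two stride-2 convolutions (kernel 19, 16 filters) with
  BatchNorm + GELU (exact erf form) between them;
* 7 stacks of [residual block; pooling residual block]; each residual
  block is two repeats of BN → GELU → dropout(0.1) → conv(kernel 17,
  stride 1, zero 'same' padding) with an additive skip, projected by a
  1×1 convolution when the channel count changes; the pooling variant
  appends a max pool (kernel 2, stride 2, ceil mode). Channels follow
  (16, 32, 32, 48, 48, 64, 64) — the filter count rises after every two
  residual blocks — and an extra 64-channel residual block closes the
  trunk;
* multi-scale taps and fusion (below); a single fully connected layer
  maps the fused features to 2 logits with SoftMax.

Ceil-mode pooling keeps short (augmented, 372-sample) inputs from
collapsing to length 0. For a 1000-sample input the length chain is
250 → 125 → 63 → 32 → 16 → 8 → 4 → 2.

**Tap placement.** "Four feature maps of different scales" cannot all be
taken after the final map (length 2); the four taps are the outputs of
the three stacks preceding the last one plus the extra block — lengths
16, 8, 4, 2 at default geometry, four genuinely distinct scales with the
deepest features still included. Each tap is adaptive-average-pooled to
fixed scale lengths (16, 8, 4, 2), which is the identity at default
geometry and well-defined for shorter inputs.

**MS-CAM fusion.** Each pooled tap X is refined by multi-scale channel
attention: a global branch squeezes X by global average pooling and
passes it through a 1×1-conv bottleneck (C → 32 → C, GELU between,
BatchNorm after) producing the channel context ω; a local branch applies
the same bottleneck shape positionwise producing L; the attention is
`sigmoid(ω ⊕ L)` (broadcast addition) and the refined map is
`X′ = X ⊗ attention`. The two branches carry separate weights, as in the
attentional-feature-fusion design this follows. Because the sigmoid is
strictly inside (0, 1), refinement never amplifies magnitude. Taps have
different channel counts (48, 48, 64, 64), so one MS-CAM instance is
built per tap with a shared bottleneck width of 32. Refined maps are
linearly interpolated (1D analogue of bi-linear up-sampling,
endpoint-preserving) to the longest scale length and channel-concatenated
before the head.

The default architecture has 1,179,042 trainable parameters, within 16%
of the ~1.02 M print of the reference design; the head width, skip
projections and adaptive-pool targets are not pinned down by that
reference, so the count is treated as a soft check only.

**Engine.** The network runs on a small reverse-mode autograd engine
written on NumPy (`bcgnet.nn`): tensors record their parents and a
backward closure; convolutions are computed via stride-tricks windows and
einsum. Every operation's gradient is verified against central finite
differences in the test suite. Weight initialisation is fan-in-scaled
Gaussian (`sqrt(2/fan_in)`) from an explicitly seeded generator; dropout
draws from a model-owned seeded stream, so identically-seeded runs are
bit-identical.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8) on cross-entropy, batch size 128.
Early stopping monitors the validation loss and halts when it has not
improved for 10 consecutive epochs (the monitored quantity is a choice;
the reference protocol names only "validation performance"); the weights
of the best validation epoch are restored. The default learning rate is
the production value 1e-5. Desk-scale experiments (a 2000-segment
cohort, a reduced 3-stack model) use 1e-3 and a handful of epochs: at
that scale the production rate would need orders of magnitude more
epochs to move the loss, and the easy synthetic cohort saturates within
2–4 epochs at 1e-3.

Cross-validation supports both segment-wise and subject-wise fold
assignment. Subject-wise is the package default because segment-wise
splitting of overnight recordings leaks subject identity across folds;
segment-wise mode is provided for comparability with protocols that
split at the sample level. Each fold's held-out part doubles as the
early-stopping validation set and the metrics are arithmetic means over
folds.

Metrics: accuracy, sensitivity, specificity and precision from the
confusion counts with hypertensive as the positive class; both the
positive-class F1 and the macro (unweighted two-class mean) F1 are
reported, since "macro F1" is sometimes printed with the binary formula;
ROC-AUC via `sklearn.metrics.roc_auc_score` (trapezoidal over all
thresholds). Ratios with zero denominators are flagged undefined and
surfaced as NaN.

## Grad-CAM and region-correlation metrics

The 1D Grad-CAM of a segment for class c takes the gradient of the
*pre-SoftMax* logit c with respect to a chosen convolutional feature map
(evaluated in inference mode), averages it over positions to get channel
weights, forms the ReLU of the channel-weighted activation sum,
up-samples linearly to the input length and min-max normalizes to
[0, 1]. An all-zero post-ReLU map is returned as-is with a `degenerate`
flag. Min-max normalization is required because the significance
threshold (0.5) is defined on the normalized scale; it also makes the
map invariant to positive rescaling of the downstream head.

**Layer choice.** The API default is the last convolutional feature map
(the extra residual block), the conventional Grad-CAM target. For
*region-correlation analysis* the layer must temporally resolve the
structure under test: at default geometry the deepest map has length 2
(one value per 500 input samples) and in the reduced desk-scale model
length 32 (31 samples per value, the size of a whole neighborhood
window), with a receptive field spanning essentially the entire segment.
Empirically, saliency at mid-depth layers (e.g. the second stack,
≈ 8 samples per position) concentrates sharply on J-neighborhoods in a
trained model, while the deepest map does not resolve them. The
localization analysis therefore uses a mid-depth layer, selected
explicitly; this is a resolution requirement, not a tuning of the
metrics.

The three region metrics compare the significant set
S₀.₅ = {x : heatmap(x) > 0.5} with the union N of J-peak neighborhood
windows: IoU = |S∩N| / |S∪N|; the localization rate LR partitions the
segment into consecutive window-sized chunks (trailing partial chunk
dropped), calls a chunk significant when strictly more than 50% of its
samples are significant, scores a significant chunk as a hit when
strictly more than 50% of its samples lie in N, and reports H/(H+M); the
significant rate SR is the fraction of neighborhood regions with
strictly more than 50% significant samples, counting overlapping regions
separately. All comparisons are strict (a tie at exactly 50% is
negative), matching the word "exceeds". 0/0 cases are flagged undefined
and excluded from cohort averages with their count reported, never
coerced. The window sweep evaluates window sizes {21, 31, 41, 51}
(radii 10, 15, 20, 25) with per-segment averaging.

## Problem sizes used by the test suite and acceptance script

The bundled end-to-end experiment trains the reduced 3-stack network on a
2000-segment cohort (10 + 10 subjects, ~17 min of signal each,
subject-wise 80/20 split, learning rate 1e-3, ≤ 4 epochs); it reaches
≥ 0.99 held-out accuracy. The simulator calibration draws 1000 subjects
per class and checks the cohort mean heart rates within two standard
errors. Oracle equivalences (MS-CAM equations, Grad-CAM finite
differences, region-metric brute force over 1000 random instances) run
on small tensors in seconds.

## Known limitations

* The synthetic class contrast is generous by construction; accuracy on
  this cohort says nothing about clinical discriminability.
* The NumPy engine is CPU-only and single-threaded beyond BLAS; it is
  sized for desk-scale experiments, not for full-scale corpora.
* The augmented-input model and the raw-input model are different
  networks (input lengths 372 vs 1000); heat-maps of an
  augmented-input model live on the concatenated axis, not the original
  time axis.
* Fixed `max_beats` truncation discards beats beyond the twelfth in
  fast-heart-rate segments.
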