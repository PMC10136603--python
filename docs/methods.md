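# Methods

## The model

`eegcube` implements a subject-dependent EEG emotion-recognition pipeline
built around a spatio-temporal image representation of raw amplitudes.

**Grid representation.** A 62-channel extended 10–20 montage is mapped
injectively onto a 9×9 integer grid (row 0 anterior, column 0 left
hemisphere; 19 cells remain empty).  The mapping lives in a plain-text
file (`NAME<TAB>row<TAB>col`) packaged as `seed62` and fully overridable;
the file, not code, is the source of truth.  This direct grid assignment
distorts true scalp geometry slightly (no azimuthal projection is
attempted), but preserves adjacency and left/right symmetry.  Empty cells
carry a mask, never a fill value — 0 µV is a legitimate amplitude.

**Interpolation.** Each time sample is a sparse frame; empty cells are
filled by Gaussian RBF interpolation with nodes at the occupied cells.
The interpolant reproduces node values exactly (to solver precision; the
suite enforces 1e-6 relative).  The shape parameter ε defaults to 1.0 in
grid-cell units — the kernel decays to 1/e one cell away, a locality that
keeps the 62×62 system well-conditioned (condition number checked; ε below
~0.15 on this grid is rejected as ill-conditioned).  Because the node set
is fixed per montage, the solve is precomputed once and every frame costs
one matrix product; interpolation composed with the resize is a single
(H′·W′)×62 linear operator.

**Resize and stacking.** Frames are resized 9×9 → 64×64 by bilinear
interpolation under the align-corners convention (output j at source
position j·(n−1)/(m−1)); weights are convex, so constants are reproduced
and no overshoot occurs.  w consecutive frames stack into one block
(default w = fs, i.e. 1-s windows; stride defaults to w, non-overlapping;
trailing partial windows are dropped).  Interpolation is purely spatial,
applied independently per sample — the data are uniformly sampled and no
temporal resampling is performed.  Amplitudes are z-scored per recording
(mean 0, SD 1 over all channels and samples) before interpolation, on a
switch that defaults on: CNN training needs bounded inputs, and the switch
records the decision.  Blocks are replicated onto three identical leading
channels to match the RGB input layout of the video backbone.

**Backbone.** A 3D MobileNet-style network: full 3×3×3 stem convolution,
stride (1,2,2), then five stages of depthwise-separable blocks (depthwise
3×3×3 + BN + ReLU, pointwise 1×1×1 + BN + ReLU) with repeats
[1, 2, 2, 6, 2] and a stride-2 first block per stage (last stage stride
1), ending in a global average pool.  Padding is "same"-style with
ceil-mode output extents and the larger half of the padding after — this
is what takes the temporal extent 200 → 100 → 50 → 25 → 13 and forces the
reference output shapes (stem 32×200×32×32 … stage5 1024×13×2×2, pooled
1024).  A width multiplier scales every channel count (0.25 → 256-d pooled
features) so a desk-scale network exercises every contract; convolutions
carry no bias (BN absorbs it) and no dropout is used.  The whole network,
including backward passes and Adam, is implemented in numpy; analytic
gradients are verified against central finite differences in the suite.

**Head and training.** The dense head is Dense1 (1024, linear) → Dense2
(256, ReLU) → Dense3 (120, ReLU) → Dense4 (K, softmax); Dense1 is read as
the first trained layer mapping the pooled feature to 1024 units, and its
activations are the deep features handed to the decision heads.  Training
uses Adam (lr 1e-4), cross-entropy, batch 4, shuffling, up to 200 epochs
by default, with an 80:20 per-subject train/test split and a fixed seed;
the returned model is the epoch with the lowest training loss.  With
`freeze_backbone=True` every backbone array — weights and BN statistics —
is bit-identical before and after training (enforced by checksum); the
head is then trained on once-computed cached features, which is arithmetic-
identical to re-running the frozen forward pass each epoch.

**Pretraining and the frozen-backbone question.** The transfer-learning
recipe freezes a backbone *pretrained* on a large gesture-video corpus;
such weights are an optional input (`pretrained_weights`), never bundled.
When they are absent the pipeline trains backbone and head end-to-end
instead.  This is deliberate: a frozen *randomly initialized* backbone of
this depth is measurably in the chaotic regime — small input differences
grow ~14× through the 26 conv layers — so its pooled features amplify
per-block noise and cap even an oracle linear classifier near 40% on the
default synthetic task (≈85% noise-free).  Freezing is therefore coupled
to actually having pretrained weights; the frozen-training contract itself
(backbone immutability) holds and is tested whenever freezing is on.
A freshly built backbone also has its BN running statistics calibrated on
the training inputs once, before any freezing (`calibrate_bn`): random
initialization starts from mean-0/var-1 running stats that bear no
relation to real activation scales, and without calibration eval-mode
activations decay by orders of magnitude through the heavily padded late
stages.  Pretrained checkpoints carry their own trained statistics.

**Decision heads.** The ELM draws a single random hidden projection
(uniform(−1,1) weights and biases, sigmoid activation; hidden width 1000,
ridge λ = 1e-3 by default) and solves β = (HᵀH + λI)⁻¹HᵀY in closed form
against one-hot targets; λ = 0 with an ill-conditioned system falls back
to the pseudoinverse with a warning.  Prediction ties resolve to the
lowest class index.  k-NN, SVM, random forest and gradient-boosted trees
are adapters over scikit-learn/xgboost behind the same fit/predict
contract, seeded where stochastic.  Grid search is exhaustive over the
declared grid on a stratified validation split carved from the training
side only (never the test 20%); ties take the first declared cell, and a
failing cell records a null score and continues.  The grids are package
defaults, not claimed historical ones.

**Mode filter.** Output label streams at 1-s resolution are smoothed by
replacing each label with the mode of the ORIGINAL labels in a centered
window (default tie policy: keep the original label — a tie carries no
evidence to overturn the classifier; a lowest-class policy and a cascading
left-to-right variant exist behind flags).  Windows truncate at trial
boundaries rather than padding or crossing them: emotions do not continue
across film clips.  Whether the historical filter was centered or
trailing, cascading or not, is not documented; the centered non-cascading
form is the default because it is order-independent and reproducible.  For
trial-constant truth with iid per-label correctness p, the interior
window-5 filtered accuracy is P(Bin(5, p) ≥ 3) — 0.94208 at p = 0.8 — and
accuracy is non-decreasing in window size for p > 1/2; both are enforced
statistically in the suite.

**Metrics.** Confusion matrices are rows = actual, columns = predicted.
Multiclass accuracy/precision/recall/F1 are computed one-vs-rest with
macro (unweighted) averaging — this is the convention that reproduces the
published 0.82 / 0.89 macro figures from the published pooled matrices.
Zero-denominator classes yield metric 0 with a logged warning.  Subject
summaries are the arithmetic mean and *population* SD (divisor n) of
per-subject accuracies, with optional exclusion of outlier subjects.

## Synthetic corpus

The generator emulates the structure of the restricted emotion-EEG
corpora: 15 subjects × 3 sessions × 5 trials per class per session, 62
channels at 200 Hz, trial-constant labels; trials default to 60 s (a
desk-scale stand-in for multi-minute film clips).  Each class is a
spatio-spectral signature: band-limited sinusoids (theta 6 / alpha 10 /
beta 20 Hz) with amplitude 2.5 µV at a class-specific focus region (left
frontal / right frontal / occipital / temporal), attenuated to 0.15×
elsewhere, over unit-amplitude 1/f Gaussian noise, with a per-subject
multiplicative gain ~N(1, 0.3²) and small per-trial frequency jitter and
random phases.  Classes differ in *where* and *in which band* power
concentrates, never by a mean offset, so the encoder and CNN must exploit
the arrangement.  Everything is a pure function of
(corpus seed, subject, session, trial, label).

What it does not emulate: volume conduction, artifacts (blinks, EMG),
nonstationarity, inter-channel noise correlation, realistic spectra beyond
1/f.  Passing tests therefore demonstrate that the pipeline recovers a
planted, well-posed spatio-spectral signal — not performance on real EEG.

## Problem sizes and numerics

Tests and the acceptance script use scaled-down configurations chosen as
the package's own desk-scale defaults: the end-to-end experiment runs 2
subjects × 1 session × 3 trials per class × 10 s at w = 50, 32×32 frames,
width 0.25, 20 epochs, Adam lr 4e-3, batch 16 (larger batch and lr than
the full-scale recipe, appropriate for the smaller network and dataset).
The full-size architecture is exercised by shape propagation plus one CPU
forward pass.  Numerical choices: float32 network arithmetic, float64
interpolation and ELM algebra; BN eps 1e-5, momentum 0.1; Adam
(0.9, 0.999, 1e-8); RBF condition-number guard at 1e12; ELM oracle
agreement enforced at 1e-6 and RBF at 1e-8.

## Known limitations

- No subject-independent (cross-subject) evaluation mode.
- Block-level 80:20 splitting lets temporally adjacent blocks of one clip
  straddle train and test — an optimistic bias; `split_by="trial"` is the
  stricter alternative.
- EDF export of the synthetic corpus is not provided (no EDF writer
  dependency); MAT and CSV are.  EDF *reading* is supported.
- The packaged 9×9 layout is a faithful reconstruction of the standard
  row structure, flagged as a convention: the historical cell-by-cell
  assignment is not published in machine-readable form.
- No probabilistic smoothing (HMM/Viterbi), probability calibration, or
  spectral (band-power) features — the pipeline feeds raw-amplitude frames
  by design.
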