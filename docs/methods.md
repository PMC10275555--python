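# Methods

`sleeparousal` implements a hybrid single-lead EEG sleep-arousal detector:
time-frequency images of short EEG windows are summarised by a deep
convolutional feature extractor, and a soft-margin RBF support-vector
classifier — whose hyperparameters are tuned by a Grey Wolf Optimizer —
makes the window-level arousal / non-arousal decision.  This note records
the model, its assumptions, the tunable parameters, and the design choices
made where the design was genuinely open.

## The detection problem

A cortical arousal is a brief (seconds-scale) interruption of sleep visible
on the EEG as an abrupt frequency shift toward theta/alpha rhythms and
activity above 16 Hz, against a delta-dominant sleep background.  The
detector operates on a single EEG lead sampled at 200 Hz, annotated with
intervals labelled 1 (arousal), 0 (non-arousal) or −1 (undefined; such
regions are excluded from training and scoring).

## Synthetic records

The generator (`signal_model`) builds records as mixtures of band-limited
Gaussian processes, one per clinical band (delta &lt;4 Hz, theta 4–8, alpha
8–12, beta 12–30, gamma &gt;30 Hz; synthesis uses 0.5–4 and 30–48 Hz at the
extremes to stay DC-free and below Nyquist).  Defaults:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 200 Hz | clinical PSG EEG convention |
| background band powers (δ/θ/α/β/γ) | 1 / 0.35 / 0.20 / 0.10 / 0.04 | delta-dominant sleep background |
| arousal band powers | 0.25 / 0.80 / 1.00 / 0.70 / 0.30 | elevated theta/alpha and &gt;16 Hz activity |
| background / arousal RMS | 20 / 28 µV | typical scalp EEG amplitudes |
| arousal duration | U(5, 30) s | clinical descriptions of arousal length disagree (3–15 s events up to ~30 s minima are all quoted); the configurable 5–30 s range deliberately spans windows both shorter and longer than events |
| onset/offset ramp | 50 ms raised cosine | keeps the waveform continuous at event edges |

Each band process is unit-variance Butterworth-filtered (4th order,
zero-phase) white noise, so relative band powers equal the configured
weights by construction; arousal intervals are cross-faded in.  Every
stochastic operation is a pure function of (configuration, seed).

Motion-like noise is emulated as Gaussian noise low-passed below 3 Hz
(large slow baseline excursions) and scaled so the requested SNR in dB
holds exactly.

**What the generator does not emulate:** real sleep-stage structure,
spindles/K-complexes, inter-subject variability, electrode artifacts, and
the heavy class imbalance (~4% arousal) of clinical recordings.  The
default pipeline study uses 2 events of 5–15 s per 52 s record, giving a
roughly 40/60 class split so that 10-fold stratified evaluation is
well-posed at ~400 windows.  Passing tests therefore demonstrate that the
pipeline machinery recovers a spectrally defined arousal signature, not
clinical-grade performance on hospital PSG.

## Subband decomposition

A Daubechies-3 discrete wavelet filter bank splits the lead into the five
clinical bands.  Each detail/approximation component is reconstructed to
signal length with all other coefficients zeroed; linearity guarantees the
components sum back to the input (tested to 1e−8 relative, observed ~1e−15).
A component is assigned to the clinical band containing its nominal centre
frequency.  At 200 Hz a 3-level transform bottoms out at 12.5 Hz and cannot
isolate delta, so the default depth is 5 (A5 &lt;3.1 Hz → delta, D5 → theta,
D4 → alpha, D3 → beta, D2/D1 → gamma); `level=3` remains available.

## Windowing

Windows are 1 s with 50% overlap by default (`floor((L−W)/H)+1` windows).
A window is labelled 1 when ≥50% of its span lies in arousal intervals,
−1 if it touches any undefined region (then excluded), else 0.  The 50%
coverage threshold is a symmetry choice; the label rule is monotone: growing
an arousal interval can only turn 0-windows into 1-windows.

## Spectrograms

Each window is transformed with a rectangular-window STFT (defaults
seg_len 64, hop 8, DFT length 64 — 18 frames per 1 s window at 200 Hz,
3.125 Hz bins).  Power is one-sided with interior bins doubled, so each
frame satisfies Parseval's identity exactly.  Rendering applies
10·log10(power + ε) with ε **relative** to the peak power (10⁻¹² · max);
a relative ε keeps rendering exactly invariant to overall power scaling,
which an absolute floor would break.  Min–max normalisation maps to [0, 1]
(a constant spectrogram maps to zeros), followed by bilinear resampling to
the backbone input size (299×299 full scale, 75×75 tiny).

## Feature extractor

The backbone follows the Inception-ResNet-v2 topology: Inception-v4-style
stem; residual Inception blocks A (35×35 grid at full scale), B (17×17) and
C (8×8) with branch-concatenation, a depth-matching 1×1 convolution, scaled
residual addition (0.17 / 0.10 / 0.20) and ReLU; two reduction blocks; a
final 1×1 convolution to 1536 channels and 2-D global average pooling — the
feature tap.  Convolution/batch-norm/pooling and the full reverse-mode
backward pass are implemented directly on NumPy arrays (im2col + BLAS), and
verified against central finite differences in float64.

Two scales share the graph: **full** (299×299 input, repeats 5/10/5,
1536-dim features) and **tiny** (75×75, 1/8 width, repeats 1/2/1, 192-dim),
the latter sized for CPU-scale training and testing.  Grayscale spectrogram
images are replicated to 3 channels at the input.  Inner filter counts and
residual scales follow the canonical reference convention.

Fine-tuning attaches a temporary softmax head, minimises full-batch
cross-entropy through the whole network (SGD or RMSProp, learning rate
0.001), and discards the head.  Because a randomly initialised network
carries placeholder batch-norm running statistics, the extractor exposes a
`calibrate` step that pins running statistics to the activations of one
deterministic forward pass over the data; extraction itself always runs in
evaluation mode and is bit-reproducible.  The default pipeline fine-tunes
the tiny backbone for 30 epochs with RMSProp: frozen random-init features
at 1/8 width were measured to carry essentially no class signal (a linear
probe scores ~53%), whereas 30 epochs suffice for a cleanly separable
feature space on the synthetic task.  The frozen path remains available
(`finetune_epochs=0`).

## Grey Wolf Optimizer

Bounded continuous minimisation with the canonical update: the three best
solutions (α, β, δ) each propose `X_L − A·D_L` with `A = 2a·r1 − a`,
`C = 2·r2`, `D_L = |C·X_L − X|`; a wolf moves to the mean of the three
proposals, clamped to the box; `a` decays linearly from `a_init` (2.0 by
default, 2.5 accepted) to 0.  Leaders are replaced only by strictly better
solutions, so the alpha trace is non-increasing.  `n_restarts` (default 10)
independent packs are run and the best alpha returned.  An optional
Gaussian perturbation of ω-wolves (probability 0.25, scale 0.5·box-width)
is provided but off by default: it is not part of the canonical update and
no defining equations exist for it, so it is exposed only as a flag.

## Classifier

The C-SVC dual with Gaussian kernel `K(x,x′) = exp(−‖x−x′‖²/(2σ²))` is
solved by scikit-learn's SVC behind the package surface; predictions are
evaluated directly from the stored support vectors, dual coefficients
`a_i y_i` (with `0 ≤ a_i ≤ C`, `Σ a_i y_i = 0`) and bias, so a saved model
file is self-contained.  The width parameter is expressed as γ = 1/σ and
searched on γ ∈ [1, 30] with C ∈ [1, 50]; the kernel exponent coefficient
is γ_eff = γ²/2.

**Standardisation.** Features are z-scored with training-fold statistics
and additionally scaled by 1/√d, giving standardised rows ~unit norm so
that squared distances between samples are O(1) *independent of the feature
dimension*.  This makes the same γ box meaningful for 2-D toy data and
192/1536-dim CNN features alike; without it, median squared distances of
~380 at d=192 drive the kernel matrix to the identity for every γ ≥ 1 and
the classifier degenerates to the majority vote.  The kernel formula is
unchanged; the scaling lives entirely in the stored standardisation
vectors.

**Tuning.** The GWO cost is the mean misclassification rate over stratified
k-fold cross-validation (folds fixed per tuning call, so the cost is
deterministic in the candidate).  The search is repeated 5 times (pipeline
default 2) from distinct seeds; the lowest error wins, ties broken toward
smaller C (the simpler model).

## Evaluation

Accuracy, sensitivity and specificity are the standard confusion-matrix
ratios; a zero denominator raises an explicit undefined-metric error rather
than returning 0.  The ROC area is the Mann–Whitney pairwise statistic
(ties = 0.5), which equals trapezoidal ROC integration; both routes are
compared in tests.  Stratified k-fold assignment preserves class
proportions and is deterministic per seed.

The pipeline tunes (C, γ) once on the full window set by inner-CV error and
then scores fresh fits on each of 10 outer stratified folds, pooling
decision values for the ROC.  This mirrors a tune-then-evaluate protocol
rather than fully nested cross-validation; on data where tuning has any
freedom to overfit the inner CV, reported outer-fold metrics would be
slightly optimistic.

## Problem sizes and numerical choices

- Default pipeline study: 4 records × 52 s → 412 windows of 1 s at 50%
  overlap; tiny backbone; GWO budget pop 10 × 20 iterations × 2 repetitions
  with 5 inner folds; 10 outer folds.  A full run takes on the order of a
  minute on one CPU core.
- Network arithmetic is float32; gradient checks run in float64.
- Batch-norm ε = 1e−3, momentum 0.1; He-normal weight initialisation.
- GWO boundary handling: clamping (preserves the documented search box).
- DWT reconstruction tolerance 1e−8 relative; STFT Parseval 1e−9; AUC
  equivalence 1e−12.
- Degenerate inputs: constant spectrograms render to all-zero images;
  annotation normalisation merges abutting equal-label intervals; zero-std
  features standardise with unit scale.

## Known limitations

- The synthetic task is separable by construction; headline metrics from
  the default run characterise the machinery, not clinical difficulty.
- Full-scale training from scratch is supported by the same code path but
  not exercised in tests (hours of CPU time); the full scale is validated
  through architectural checks (feature dimension, input-size rejection,
  determinism).
- No artifact rejection, re-referencing or notch filtering; single channel
  only; no probability calibration of the SVM decision values.
- EDF reading is optional (requires `mne`); the package's own container is
  a text header plus raw float32 payload with a TSV annotation sidecar.
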