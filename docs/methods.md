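# Methods

This note documents the models implemented in `neurotwin`, the synthetic
data they are exercised on, the numerical choices behind them, and the
limits of what the package's tests demonstrate.

## Overview

The package implements the computational core of a multimodal brain
digital twin: a continuously updated patient model that couples episodic
structural MRI snapshots with streaming functional EEG.  Five stages are
chained: (1) EEG denoising and windowing, (2) spectral feature extraction
into a two-term Functional Health Vector, (3) a BiLSTM decoder of
cognitive state, (4) a patch-transformer tumor analyzer with
attention-entropy regularisation and adaptive thresholding, and (5)
feature-level EEG–MRI fusion with a composite risk score, plus an
exponential tumor-kinetics engine operating on longitudinal volumes.
Everything runs on synthetic data produced by `neurotwin.synthgen`, so
the whole pipeline is testable without any recording or scan.

All trainable components (BiLSTM, transformer, fusion MLP) are built on
a small reverse-mode automatic-differentiation core over numpy arrays
(`neurotwin._autodiff`, `neurotwin.nn`).  The engine implements exactly
the primitives these models need and is gradient-checked against central
finite differences in the test-suite.  Training is deterministic under a
seed and runs in seconds-to-minutes on one CPU at the desk scales below.

## Synthetic data: what it emulates, what it does not

**EEG.**  Each cognitive state is rendered as its canonical rhythm on
every channel: ~10 Hz alpha for *Relaxed* (drawn from 9–11 Hz), 15–25 Hz
beta for *Stress*, 4.5–6.5 Hz theta for *Fatigue*, with per-channel
random phase and ±20 % amplitude jitter around a 10 µV default.
Channels are contaminated by (i) a shared EOG reference — Poisson blinks
(0.25 /s) shaped as 150 ms Gaussian deflections of ~60 µV plus slow
sub-0.5 Hz drift — mixed in with gain 0.8, (ii) a 15 µV power-line
sinusoid (50 or 60 Hz), and (iii) white sensor noise (2 µV SD, clean
laboratory conditions).  The EOG reference is deliberately a sub-4 Hz
process: ocular artifact is removed by decorrelation against the
reference, not by spectral filtering, so it must overlap the EEG band of
interest after bandpassing.  The generator returns the clean rhythm and
the EOG reference separately, which is what makes SNR oracles possible.

What it does *not* emulate: 1/f background spectra, non-stationary
rhythm amplitude, volume conduction/channel correlation structure,
muscle artifact, electrode pops.  Consequently the three states are far
more spectrally separable than in recorded EEG; the decoder results
below certify the pipeline's correctness, not clinical performance.

**MRI phantoms.**  64×64 grayscale slices (16 patches of 16×16):
uniform 0.25 background, Gaussian pixel noise (SD 0.05), and zero or one
bright disc (+0.35 intensity) with radius drawn from 12–20 px.  The
radius range spans 0.75–1.25× the patch size because the ground truth is
defined at patch resolution: a patch is labelled tumor iff the disc
covers more than half its area, and discs much smaller than a patch can
never satisfy that rule.  Texture, anatomy, partial-volume effects and
scanner artifacts are absent — the phantoms test the machinery
(tokenisation, attention, thresholding, masks), not radiology.

**Volumes.**  V_i = V0·exp(SGR·t_i) + ε_i with ε ~ N(0, 3 cc²) redrawn
when a volume would be non-positive; defaults are V0 = 50 cc,
SGR = 0.014 /day (the clinically reported glioblastoma specific growth
rate), 151 daily measurements.

## EEG chain

Bandpass: 4th-order Butterworth, 0.5–45 Hz, applied forward–backward
(zero phase).  Notch: quality-30 IIR at 50/60 Hz, also zero phase.  EOG
removal: single-tap LMS per channel against the shared reference,

    e_c(t) = y_c(t) − a_c(t)·r(t),   a_c(t+1) = a_c(t) + µ·e_c(t)·r(t),

with µ = 0.01 and, by default, normalisation of the update by a running
estimate of the reference power (NLMS), which makes the effective step
size independent of EOG amplitude.  The plain recursion is available
(`normalized=False`) and is checked bit-for-bit against a per-sample
reference implementation.  The steady-state coefficient fluctuates
around the least-squares projection ⟨y,r⟩/⟨r,r⟩ with variance
proportional to µ; convergence tests therefore read the tail
time-average of the coefficient trajectory rather than its last sample.
A coefficient exceeding 10⁶ raises a stability error naming µ.

Windowing: length L ∈ [2, 5] s, step 0.5·L (50 % overlap, i.e.
(L−S)/L = 0.5), anchored at t = 0, trailing partial window dropped.
Supervised labels use the schedule state at the window midpoint.

SNR is 10·log₁₀(P_clean/P_residual) with residual = signal − clean; a
zero residual reports a 300 dB cap instead of +inf.

## Spectral features and the Functional Health Vector

Band powers (Theta 4–7, Alpha 8–12, Beta 13–30 Hz) are rectangle-rule
integrals of a Welch PSD (Hann taper, segment = half window, so a 2 s
window still resolves 0.5 Hz after halving) averaged over EEG channels.

The spectral balance is FB = σ(log(α/β) − log(θ/α)) with the logistic σ:
monotone up in α/β, down in θ/α, bounded in (0, 1).  FB nears 1 under
alpha dominance (relaxed), 0 under beta (stress) or theta (fatigue)
elevation.

The Functional Health Index is a weighted mean of K = 5 features —
relative θ/α/β power and the two spectral ratios — each min-max
standardised against a patient baseline (≥ 10 reference windows) and
clipped to [0, 1], so FHI ∈ [0, 1] and is invariant to weight rescaling.
Default weights (1, 2, 1, 1.5, 1) give alpha-linked features the
largest say.  The two ratio features enter on the **log scale**: raw
band-power ratios are heavy-tailed, and a single high-ratio baseline
window would otherwise dominate the min-max range and squash the
standardised values of every ordinary window toward zero (empirically
this halves the Stress–Fatigue FHI separation).  Zero denominators are
guarded by ε = 10⁻¹² and flagged degenerate rather than dropped.
FB and FHI are computed independently of each other (disjoint).

## BiLSTM state decoder

Input sequences are T×2 matrices of (FB, FHI); the default sequence is
30 consecutive windows from a single synthetic subject.  Two stacked
bidirectional LSTM layers (64 units per direction; forget-gate bias
initialised to 1) produce h_t = [h_t→ ‖ h_t←] ∈ R¹²⁸, mapped by a dense
softmax head to probabilities over (Relaxed, Stress, Fatigue); the
decoded state is the argmax with ties broken in that fixed order.
Training is full-batch Adam (lr 10⁻³) on categorical cross-entropy, at
most 150 epochs with early stopping (patience 25) on validation
macro-F1, restoring the best parameters.  The cap was raised from an
initial 50-epoch/patience-8 configuration after observing that short
patience frequently halts the optimiser on its initial plateau.
Evaluation reports the row-normalised confusion matrix, per-class
precision/recall/F1 and macro-F1 through the package's own arithmetic,
cross-checked against scikit-learn in the tests; a class absent from the
labels is reported as undefined and excluded from the macro average.

## Patch transformer with PLAR and adaptive thresholding

Slices are cut into non-overlapping P×P patches (P = 16), flattened,
linearly embedded and given fixed sinusoidal positional encodings; the
patch order is row-major and the inverse patch→pixel mapping is exact.
Images not divisible by P are rejected; an explicit `center_crop`
preprocessing op produces the largest divisible region (600×600 → 592×592)
— never silent padding.  The encoder is a pre-norm multi-head
self-attention stack; all L·H post-softmax attention matrices are
captured for regularisation and diagnostics (no dropout, for
determinism).  Two profiles exist: `paper` (12 layers, 8 heads) and
`desk` (4 layers, 4 heads, embedding 32, 150 epochs) — the desk profile
is what the package's own evaluations run.

A linear head shared across patches yields tumor probabilities p_i.  The
training loss is L_CE + λ₁·L_PLAR with λ₁ = 0.6, where
L_PLAR = −mean over all layers, heads and query patches of the attention
row entropy H_i = −Σ_j α_ij log(α_ij + ε), ε = 10⁻⁸.  Minimising the
total therefore rewards spatially diverse attention (L_PLAR ∈ [−log N, 0]).
Optimisation is minibatch Adam at lr 10⁻⁴ (batch 64).

**Adaptive threshold.**  At inference the mask rule is M_i = 1 iff
p_i > θ with θ = μ_bg + k·σ_bg (k = 1.5), the background statistics
taken over patches at or below the median probability (configurable
percentile; tumors occupy a minority of patches, so the lower half is
background-dominated).  A slice whose probabilities are all identical is
degenerate: θ equals that value and the mask is empty.  θ is strictly
increasing in k.

**Slice-level classification.**  Slice truth is "any ground-truth tumor
patch".  The package's slice prediction is the standard decision on the
probability map, max_i p_i > 0.5.  An "any adaptive-mask patch" rule is
also implemented but is *not* the default because it degenerates on a
well-trained model: background probabilities saturate near zero, σ_bg
collapses, θ → μ_bg, and the mask flags the above-median background
patches of every slice — measured slice accuracy falls to chance while
the same probability maps are perfectly separable at the 0.5 boundary.
The background-statistics threshold is an anomaly detector for scans
whose background probabilities are broad (the regime of its reference
statistics, μ_bg ≈ 0.2–0.32); it is kept as the segmentation/mask rule,
and per-slice Dice of those masks is reported alongside accuracy.

Saliency is Grad-CAM style: the slice-level tumor score (mean tumor–
background logit margin) is backpropagated to the final-layer tokens;
channel weights are token-averaged gradients, and the rectified weighted
activation map is min-max normalised onto the patch grid.  Patch masks
convert to volume as (tumor patches)·P²·pixel-area·slice-thickness.
The 64-dim structural embedding used by fusion is the mean-pooled
final-layer token vector passed through a linear projection.

## Packet gate and fusion

Feature packets (UTC timestamp, device, session, features incl. FHI,
HMAC-SHA256 over a canonical sorted-key JSON payload) are validated in
the order device-registry → signature (constant-time compare) →
staleness (age > 3 s rejected); every input yields accept or a
categorised reject.  The risk gate is a two-class softmax R =
softmax(Wx+b) restricted to the high-risk component — trainable as a
logistic regression on labelled packets — and packets are forwarded iff
R > 0.75, strictly.

Fusion concatenates (S ‖ FHV), S first, and applies an MLP
66 → 128 ReLU → 64 ReLU → 64 linear to produce Z(t); a single logistic
unit on Z(t) gives the composite risk, trained jointly with the MLP on
labelled pairs (the aggregation into a single score is learned, not
hard-coded).  Stream alignment pairs each FHV with the latest scan whose
timestamp ≤ the FHV's; earlier FHVs stay unpaired.

## Tumor kinetics

V(t) = V0·e^(SGR·t) is fitted by log-linear least squares (closed form,
stable); SSE/MSE/RMSE/R² are reported on the natural volume scale
against the back-transformed curve, with MSE = SSE/n.  95 % prediction
intervals use the log-scale OLS prediction variance with t(n−2)
quantiles, back-transformed, hence multiplicative, widening with
horizon, and exactly degenerate for noise-free data.  A fit needs ≥ 3
points; the exact two-point exponential is available as a closed-form
helper.  Only the exponential family is implemented; polynomial trend
fitting is out of scope.  The module follows the Model/Results idiom
(`ExponentialGrowthModel.fit()` → results with `summary()`, `forecast()`,
`plot()`); the rest of the package keeps estimator-style classes and a
CLI, the natural shape for a multi-stage pipeline tool.

## Study conditions for the reported benchmarks

The benchmark experiments (`neurotwin.experiments`, run by
`scripts/acceptance.py`) use desk-scale problem sizes chosen so each
completes in well under a minute of CPU:

- state decoding: 3 independent cohorts of 12 subjects per state,
  30 windows each (1080 windows per cohort, 360 per class), full chain,
  subject-disjoint 70/30 split; reported macro-F1 is the mean of the 3
  held-out scores;
- tumor phantoms: 400 slices (half with a disc), desk profile, 70/30
  split; held-out slice accuracy plus a same-seed λ₁ = 0.6 vs 0
  attention-entropy comparison;
- denoising: 30 s of clean alpha rhythm, line + EOG contamination scaled
  to exactly 0.42 dB SNR, then bandpass + notch + LMS (reaches ~11–13 dB);
- kinetics: 100 series of 151 daily points at 3 cc noise.

## Known limitations

- The autodiff core is minimal by design: no GPU, no broadcasting over
  arbitrary ops, no graph reuse; large `paper`-profile training is
  possible but slow.
- Synthetic separability means reported decoder/segmenter scores are
  ceiling-level; they validate plumbing and learning dynamics, not
  generalisation to recorded data.
- The adaptive threshold inherits the degeneracy discussed above when a
  model is confident; using it for slice-level detection requires broad
  background probabilities.
- Packet security covers integrity/staleness of individual packets;
  transport encryption, key rotation and storage are out of scope.
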