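# neurotwin

Multimodal EEG–MRI digital-twin analytics for continuous brain-health
monitoring and tumor progression modeling — a tested, reusable
implementation of the full computational chain, exercised end-to-end on
built-in synthetic data.

A *digital twin* here is a continuously updated virtual model of a
patient's brain: episodic structural MRI snapshots provide anatomy,
streaming EEG provides function, and the twin couples the two into
state estimates and risk scores.  The package is aimed at researchers
and engineers who need the algorithmic core of such a system — the
signal chain, the models, and the statistics — without hardware, cloud
infrastructure, or clinical data.

## What is implemented

**EEG chain** (`eeg_preproc`, `eeg_features`) — zero-phase Butterworth
bandpass (0.5–45 Hz) and 50/60 Hz notch; single-tap (N)LMS decorrelation
of each channel against an EOG reference,

```
e(t) = y(t) − â(t)·r(t),    â(t+1) = â(t) + µ·e(t)·r(t);
```

50 %-overlap windowing (step S = L/2, overlap (L−S)/L = 0.5); Welch band
powers in Theta (4–7), Alpha (8–12) and Beta (13–30 Hz); and the
two-term Functional Health Vector FHV(t) = {FB_t, FHI_t} with
FB = σ(log α/β − log θ/α) and FHI a baseline-standardised weighted mean
of K = 5 spectral features, both bounded in [0, 1].

**State decoder** (`state_bilstm`) — a 2-layer, 64-unit bidirectional
LSTM over FHV sequences, h_t = [h_t→ ‖ h_t←], softmax over
(Relaxed, Stress, Fatigue), trained with categorical cross-entropy;
reports per-class precision/recall/F1, macro-F1 and a row-normalised
confusion matrix.

**Tumor analyzer** (`vitpp`) — a vision-transformer-style patch
classifier (16×16 patches, sinusoidal positions, pre-norm multi-head
self-attention) with two task-specific extensions: *patch-level
attention regularisation* L_total = L_CE + λ₁·L_PLAR, where L_PLAR is
the negative mean entropy of all attention rows (λ₁ = 0.6) and counters
attention collapse; and a *background-adaptive threshold*
θ = μ_bg + k·σ_bg (k = 1.5) that turns patch probabilities into masks,
plus Grad-CAM-style saliency, mask→volume conversion, and 64-dim
structural embeddings.

**Fog gate and fusion** (`fusion_risk`) — HMAC-SHA256 packet validation
(unknown-device / integrity / staleness > 3 s), a softmax risk gate
forwarding packets with R > 0.75, timestamp alignment of FHVs to the
latest scan, and a fusion MLP (S ‖ FHV → 128 → 64 → 64) with a logistic
composite-risk head.

**Growth kinetics** (`kinetics`) — exponential kinetics
V(t) = V₀·e^(SGR·t) (default SGR 1.4 %/day, doubling time
ln 2/SGR ≈ 49.5 days) fitted by log-linear least squares, with
SSE/MSE/RMSE/R² on the volume scale and back-transformed 95 %
prediction intervals, in the Model/Results idiom.

**Synthetic generators** (`synthgen`) — state-labelled multichannel EEG
with separate clean/EOG ground truth, tumor phantoms with patch-level
labels, and noisy exponential volume series; every downstream stage is
tested against these.

The neural components run on a small, gradient-checked reverse-mode
autodiff core over numpy (`neurotwin.nn`), so the package has no deep
learning framework dependency and trains its desk-scale models in
seconds to minutes on one CPU.

## Worked example

Fit growth kinetics to a synthetic 151-day volume series (V₀ = 50 cc,
SGR = 0.014/day, 3 cc measurement noise) and forecast 60 days ahead:

```python
from neurotwin import synthgen, kinetics

series = synthgen.generate_volume_series(
    synthgen.SynthVolumeSpec(v0=50, sgr=0.014, noise_sd=3.0,
                             n_points=151, seed=3))
res = kinetics.ExponentialGrowthModel.from_dataframe(series).fit()
print(res.summary())
print(res.forecast(60).tail(1).to_string(index=False))
```

```
Exponential tumor-growth fit  V(t) = V0 * exp(SGR t)
----------------------------------------------------
observations        151
V0 (cc)             49.7720
SGR (/day)          0.014045
doubling time (d)   49.35
SSE (cc^2)          1534.8306
MSE (cc^2)          10.1644
RMSE (cc)           3.1882
R^2                 0.999005
  day  volume_cc   lower_cc    upper_cc
210.0 950.444593 887.533093 1017.815483
```

The estimated growth rate (0.01405/day) recovers the generating value
within 0.3 %, and the 95 % prediction interval at day 210 spans roughly
±7 % of the point forecast — the multiplicative uncertainty of the
log-scale fit.

The full pipeline runs end to end from the CLI:

```sh
neurotwin --seed 3 demo --outdir runs/demo
```

```json
{
  "seed": 3,
  "state_macro_f1": 1.0,
  "state_accuracy": 1.0,
  "vit_slice_accuracy": 1.0,
  "vit_mean_dice": 0.28124190624190626,
  "kinetics_sgr_hat": 0.014114363884401432,
  "kinetics_sgr_true": 0.014,
  "kinetics_r2": 0.9993079752685107
}
```

On the clean synthetic conditions the decoder and slice classifier are
at ceiling (see `docs/methods.md` for why, and for what that does and
does not demonstrate).  Other verbs: `synth`, `eeg filter`,
`eeg features`, `kinetics fit|forecast`, `fog validate` — see
`neurotwin --help`.

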