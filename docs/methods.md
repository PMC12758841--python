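# Methods

## The model

CaMPNet is a multimodal transformer for multilabel diagnosis over 13
categories (one "Normal" rhythm class and 12 cardiovascular disease
classes) from three inputs: a raw 12-lead ECG waveform (10 s at 500 Hz,
5000 samples per lead), nine machine-measured structured features
(interval timings, electrical axes, ventricular rate) with a binary
validity mask, and demographics (age, sex).

The waveform is cut into 100 non-overlapping 50-sample patches spanning
all 12 leads; each patch is linearly projected to a D-dimensional token
(a stride-equal 1-D convolution expressed as a matrix product). The nine
feature values concatenated with their nine mask bits pass through a
feed-forward network to a single feature token; age and sex each get
their own feed-forward embedding.

Fusion happens *before* encoding. The feature token queries the patch
tokens through single-head cross-attention:

    Q = X_s W_Q,   K = X_p W_K,   V = X_p W_V
    A = softmax(s · LN(Q) LN(K)^T / sqrt(D)),   Z = A V
    fused = LN(X_s + FFN(Z))

The sequence [CLS, fused, patch_1..patch_100, age, sex] receives learned
positional embeddings and passes through a pre-norm transformer encoder
(GELU feed-forward of width `ffn_mult`·D, dropout 0.1). A linear head on
the encoded CLS state emits 13 logits; sigmoid gives per-label
probabilities. The attention row `A` (one weight per patch) is returned
for interpretability.

Two departures from the plain scaled-dot-product fusion, both
configurable off (`ModelConfig.qk_norm=False` recovers the textbook
form): queries and keys are layer-normalized before the dot product, and
a fixed temperature `s` (`attn_scale`, default 1.0) multiplies the
logits. Without these, fusion-attention logits are dominated by patch
*amplitude* — QRS complexes monopolize the weights regardless of
diagnostic content — and the attention carries no usable content signal
at the scales this package trains at.

### Inference modes

* `full` — all modalities.
* `feature_masked` — the structured values *and* their mask bits are
  zeroed at inference; weights are untouched. This is the robustness
  probe for missing machine measurements and the behavior of prediction
  when no features are supplied.
* `without_age_sex` — metadata tokens absent (a train-time ablation;
  sequence length 102 instead of 104).

## Preprocessing

Waveforms: non-finite samples are zeroed, records truncated or
zero-padded to 5000 samples, then each lead is z-scored to mean 0,
population SD 1 (constant leads map to zeros). Structured features:
per-feature mean/SD are fitted on the training split only, over valid
(mask = 1) entries; missing entries are imputed with 0 and flagged by the
mask; age is z-scored against the training cohort. `TrainStats` records
the split it was fitted on, making leakage checkable. Population (1/N)
standard deviations are used throughout.

Splitting: the most recent ceil(10 %) of records by (timestamp, id) form
the temporal external test cohort; the remaining development records are
shuffled 7:1:1 into train/validation/internal test (validation and test
get round(n/9) each, the remainder goes to train).

## Training protocol

Loss: weighted binary cross-entropy over the 13 labels,

    L = -(1/C) Σ_c [ w_c y_c log σ(ŷ_c) + (1-y_c) log(1-σ(ŷ_c)) ],
    w_c = (N - n_c) / (n_c + ε),   ε = 1e-6,

with N training records and n_c positives per label, log arguments
clamped at 1e-12. Optimization is Adam with decoupled weight decay
(applied to matrices only), per-step global-norm gradient clipping
(default 1.0), and seeded per-epoch shuffling. After each epoch the
combined metric 0.5·(macro AUC) + 0.5·(macro accuracy at threshold 0.5)
is computed on the validation split; it drives a plateau LR scheduler
(decay factor 0.5 after 5 non-improving epochs under a 1e-3 relative
threshold, 2 cooldown epochs) and early stopping (patience 10). The
checkpoint with the best validation metric is restored at the end, never
the last.

Two auxiliary training components, both defaults of `TrainConfig` and
both removable:

* **Feature-token dropout** (`feature_dropout`, default 0.1; the
  scaled-down experiments below use 0.3): a fraction of training records
  sees the fully-missing feature regime (values and masks zeroed).
  Without it the model happily routes any label that is redundantly
  encoded in a structured feature through that feature alone, and
  feature-masked inference collapses for that label; with it, masked
  inference stays in-distribution.
* **Fusion deep supervision + attention-entropy regularization**
  (`aux_weight` 0.3, `attn_entropy_weight` 0.05): an auxiliary linear
  head reads the fusion token during training and receives the same
  weighted BCE, and the fusion attention's entropy is lightly penalized.
  At full data scale the fusion pathway plausibly earns its gradient
  naturally; at desk scale the encoder's direct path saturates the task
  within a few epochs, after which the fusion attention would be frozen
  noise. The auxiliary loss keeps the pooled context label-discriminative
  and the entropy term keeps the attention from hiding in uniformity.
  Both heads are ignored at inference.

## The synthetic cohort generator

The generator emulates the *data model* of a large hospital ECG archive,
not ECG physiology. Each record's beat is a sum of Gaussian bumps
(P, Q, R, S, T) on a shared template, projected to 12 leads by per-lead
gains (aVR inverted), with per-record lognormal variation of amplitudes
(~8–10 %) and gains (~5 %), RR jitter (cv 0.02 at baseline), additive
Gaussian noise (0.05 mV) and per-lead baseline wander (two sinusoids,
0.15–0.5 Hz, amplitude ~0.08 mV — the respiration/motion drift every
real ECG carries; it also prevents a constant segment offset from
degenerating into a trivially detectable global lead-mean shift under
per-lead z-scoring).

Demographics follow Normal(64.8, 17) years clipped to [18, 100] and a
52.4 % male fraction. Default label prevalences mirror a large ICU ECG
archive (Normal 39.4 %, atrial fibrillation 32.2 %, heart failure
31.9 %, ... cardiac arrest 2.0 %). Disease labels are independent
Bernoulli draws (optionally coupled through a Gaussian copula), Normal is
mutually exclusive with disease, and label-free rows are resampled.
Because that conditioning inflates marginals, the sampling probabilities
are pre-calibrated by a fixed-point iteration so the *post-conditioning*
marginals hit the targets; targets summing below 1 are infeasible under
"at least one label per record" and fall back to uncalibrated draws with
a warning.

Each disease label plants a stylized signature: parameter-level effects
(RR irregularity, PR prolongation, QRS widening, P suppression, per-lead
amplitude scaling) fold into the beat parameters before rendering, and
the signal-level ST offset adds its magnitude inside each beat's ST
window on its target leads — flat across the window, then decaying over
0.12 s across the T region (elevation merges into repolarization; an
abrupt return to baseline mid-beat would plant a spurious notch).
Interval prolongations that no longer fit the RR interval slow the rate
accordingly. The nine structured features are computed exactly from the
post-signature beat parameters (QTc by Bazett, rate = 60/RR, axes from
the limb-lead gains) — generator ground truth, never re-measured from
the signal — then each is dropped independently with the missingness
rate (default 0.05). Timestamps are strictly increasing integers; a
fixed config and seed reproduce the cohort bit-identically.

What the generator does *not* emulate: dipole/torso physiology, morphology
beyond Gaussian bumps, inter-lead timing differences, pathology-specific
waveform shapes (signatures are simple parameter or offset edits),
realistic co-occurrence structure, or drift between the development and
temporal eras. Passing tests therefore demonstrate that the pipeline's
mechanisms work as specified on data with known ground truth — not that
the model reaches any particular accuracy on real ECGs.

## Scaled-down study conditions

All end-to-end checks use a compact configuration exercising the
identical code path as the full-size model: D = 64, 2 encoder layers,
2 heads, feed-forward multiplier 2, patch length 50 (so 100 patches of a
5000-sample record). The recovery experiment trains on a 2000-record
cohort with three planted classes — atrial fibrillation (RR irregularity
+ P suppression), supraventricular/ventricular tachycardia (QRS
widening) and ST-elevation/non-ST-elevation myocardial infarction (ST
offset on V1–V4) — plus Normal, at prevalences 0.3/0.3/0.3/0.4; batch
size 64, learning rate 3e-4, up to 10 epochs, feature dropout 0.3,
three training seeds with the median reported. These classes are all
waveform-expressed at intra-patch scale. A run takes a few minutes on
one CPU core.

## Numerical choices

* float32 everywhere in the network; the loss value itself is computed
  in float64 so it matches reference implementations to ~1e-12 on equal
  inputs.
* Softmax is max-shifted; sigmoid is branch-stable; BCE clamps log
  arguments at 1e-12.
* Zero-SD guards: constant leads z-score to zeros, zero-variance
  features get SD 1, ε = 1e-6 guards all-negative label counts.
* AUC is the Mann–Whitney statistic via average ranks (ties get half
  credit); average precision groups tied scores; macro rows use
  population SD; labels with one observed class are excluded from rank
  metrics with a warning and a changed divisor.
* Platt calibrators are per-label univariate logistic regressions
  (unpenalized) fitted on validation outputs only.
* The scheduler counts an epoch as non-improving when the metric fails
  to exceed best·(1 + rel_threshold); decay fires when the bad-epoch
  count *reaches* patience.
* 7:1:1 rounding sends remainder records to train; chronological ties
  break by record id.

## Known limitations

* **Attention localization is initialization-dependent at this scale.**
  For records whose only planted signature is an ST offset, per-lead
  z-scoring necessarily spreads the offset's evidence beyond its window:
  the subtracted lead mean shifts the remaining samples coherently
  across the target leads (and baseline wander, being lead-independent,
  does not mask a lead-coherent shift), and the inflated lead SD shrinks
  normalized QRS/T amplitudes. Quiet diastolic patches and QRS landmark
  patches therefore carry genuine, often statistically cleaner, evidence
  than the window itself. The trained fusion attention is sharp and
  beat-phase-locked — it tracks the signature-bearing beat segment in
  each record — but *which* landmark wins is an initialization lottery,
  and the strict window-overlap statistic holds for only a minority of
  seeds. The heatmap export shows the qualitative behavior (concentrated
  bands on beat landmarks) regardless.
* **Feature-coupled signatures lose discriminability under masking.**
  A label whose planted effect *is* one of the nine features (e.g. PR
  prolongation for atrioventricular block) is learned from that feature;
  under full masking the model must recover a cross-patch timing cue
  that the 0.1 s patch grid makes hard at D = 64, and masked AUC for
  such labels drops substantially. The recovery experiment therefore
  uses waveform-expressed classes; this mirrors the premise that the
  waveform carries most of the diagnostic signal.
* The generator's Normal-exclusivity plus resampling makes prevalence
  targets whose sum is below 1 unattainable exactly.
* Checkpoints store weights with a config/stats/label manifest but no
  architecture migration: a checkpoint loads only into the version that
  wrote it.
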