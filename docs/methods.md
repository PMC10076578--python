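# Methods

This note documents the models, the synthetic data they are validated on,
and the numerical and design choices a maintainer would want to know.

## Problem and pipeline

The package classifies subjects, not utterances: each subject contributes
nine task-elicited recordings (six interview-style, three picture-description
style), and the decision is made from the joint evidence of all nine. The
pipeline is transfer learning in the speaker-recognition style — embedding
extractors are pre-trained for speaker discrimination on a separate
many-speaker corpus and then frozen; the clinical-style cohort only ever
passes through them forward.

## Acoustic front end

All three feature kinds share one framing convention: 16 kHz input (44.1 kHz
is resampled with a polyphase filter), pre-emphasis 0.97, 25 ms Hamming
windows at a 10 ms shift, snip-edges framing (only complete windows), so
T = 1 + ⌊(N − 400)/160⌋ frames — exactly predictable, which the tests rely
on. Dithering exists but defaults off so silence is bit-reproducible.

The 60-dimensional targets are reached as follows:

- **FBANK**: 60 triangular mel filters (20–7600 Hz), log energies floored at
  1e−10.
- **MFCC**: 20 cepstra including C0 over 40 mel filters, plus Δ and ΔΔ
  (regression window 2) = 60. A dialect with 60 static cepstra over 60
  filters is a config switch; the delta composition is the default because it
  is the most common way to reach 60 dimensions.
- **PLP**: 21 triangular Bark-scale bands (trapezoid masks are approximated
  by triangles in the Bark domain), equal-loudness weighting, cube-root
  intensity–loudness compression, cosine-transform inversion to
  autocorrelations, an order-19 all-pole fit (Levinson via Toeplitz solve),
  20 cepstra with c0 = log gain, plus Δ and ΔΔ = 60.

**VAD** thresholds per-frame log energy at mean − 0.5·sd with two guards: an
absolute silence floor (≈ −60 dBFS rms) below which a frame is never voiced,
and a 0.1-nat slack so stationary signals (whose energy sd is ~0) are not
split by numerical ripple. An utterance whose every frame fails is rejected
as degenerate rather than silently passed on. **CMVN** is per-utterance mean
subtraction; variance normalization is available but off by default, since
the embedding extractors see scale information through statistics pooling.

## i-vector model

A diagonal-covariance GMM-UBM is trained by EM from a seeded k-means
initialization; the per-iteration total log-likelihood is recorded on the
model and is non-decreasing (checked in tests, with a 1e−6 relative slack
for the variance-floor projection). Variances are floored at 1e−4 of the
global per-dimension variance. Only the diagonal model is implemented: the
total-variability algebra below needs nothing else.

Given zeroth/first-order Baum-Welch statistics (N_c, F̃_c) of an utterance,
the latent factor posterior is Gaussian with precision
L = I + Tᵀ Σ⁻¹ N T and mean L⁻¹ Tᵀ Σ⁻¹ F̃ — the MAP mean is the i-vector.
T is estimated by EM: the E-step computes these posteriors per utterance; the
M-step solves one R×R weighted least-squares system per mixture component
(ridge 1e−8 for rank safety). Initialization is seeded Gaussian scaled by
0.1·√(mean UBM variance). The expected complete-data objective restricted to
its T-dependent terms is exposed (`tv_auxiliary`) so monotonicity is testable
directly. Defaults are 256 components / rank 256; tests and the desk-scale
profile use 8/16. No length-normalization, LDA or PLDA follows: the
classifier consumes raw i-vectors (a length-norm flag exists, default off).

## Neural extractors

Both encoders are NumPy implementations with explicit backpropagation,
verified against central finite differences to <1e−7.

**TDNN**: five frame-level splice-affine+ReLU layers with contexts
{−2..2}, {−2,0,2}, {−3,0,3}, {0}, {0} — the canonical stack whose dependency
trace spans exactly 15 input frames. Statistics pooling concatenates the
time-axis mean and standard deviation (std floored at 1e−5 so constant or
single-frame inputs stay finite; the floor's gradient is zero). The
embedding is the first segment-level affine output, pre-nonlinearity —
standard x-vector practice. Default hidden widths 512×4 + 1500; the
`tiny_tdnn` profile uses 48×4 + 144 with a 64-d embedding and is what tests
and the acceptance study train.

**ResNet34**: the (1, 60, T) feature map passes a 7×7 stride-1 stem, then
four stages of basic residual blocks — repetitions (3,4,6,3), channels
(32,64,128,256), 3×3 kernels, stride 2 at stages 2–4 with a 1×1 stride-2
projection shortcut wherever the addition would not be dimension-consistent.
60 is not divisible by 8, so stride-2 convolutions use ceil-mode padding:
60→30→15→8 along frequency (the nominal F/8 of the stage table). After the
last stage the (C, F′, T′) map is flattened to C·F′ channels and pooled over
time with the same statistics pooling; a segment affine produces the
embedding. No batch normalization is used: inputs are CMVN'd, the desk-scale
nets are shallow enough to train without it, and omitting it keeps training
single-threaded-deterministic.

**Training** minimizes speaker cross-entropy over 200-frame chunks
(batch 64, AdamW, lr 1e−3; TDNN decays ×0.7 every 400 steps, the ResNet rate
is constant). Utterances shorter than one chunk are wrap-padded — training
only; extraction always forwards the full unchunked utterance, which is what
makes the fixed-length embedding claim meaningful for variable-duration
input. The exotic layer-wise-rate optimizers sometimes used for x-vector
training are substituted by decoupled-weight-decay Adam behind the config;
optimizer identity affects training speed, not the method. The desk-scale
profile trains 40 epochs — the thin layers and small corpus need more passes
than the published-scale 18/21-epoch schedules, which remain the defaults of
the `paper`-size profile.

## Multi-task stacked ensemble

Per (task, tag) an RBF-SVM is selected by inner 3-fold grid search
(C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 1e−3, 1e−2, 1e−1}) on training subjects
only, then refit with Platt-calibrated probabilities. The per-task
"classification percentage" is read as the positive-class posterior — one
scalar per (task, tag) — so fusing k embedding types gives a 9·k meta-feature
vector, tag-major task-minor. Random forests are available as the per-task
comparison classifier (grid over {100, 300, 500} trees); the ensemble
back-end proper is SVM → MLP.

Meta-features for training subjects are built **out-of-fold** (inner 5-fold
split; task models refit with the already-selected hyperparameters), so the
meta-learner never sees probabilities from a model trained on the subject it
scores. The diagram-faithful `in_sample` protocol is a switch; out-of-fold
is the default because in-sample meta-features are optimistically biased.
The MLP meta-learner is grid-searched over hidden sizes
{(16,), (32,), (64,), (32,16)} and L2 {1e−4, 1e−3}, 500 iterations. Grid
*contents* everywhere are engineering defaults: the protocol requires grids
to exist but does not pin them, and the desk-scale acceptance study uses
reduced grids (C ∈ {1,10}, γ = scale; one MLP point) to keep 100 ensemble
fits per study inside minutes.

Two comparison baselines are included: cosine-similarity nearest-centroid
voting over the nine tasks (odd count — no ties), and paired-t-test task
selection (drop any task significantly worse than the best-ranked task at
α = 0.05 over per-fold CV accuracies; a degenerate zero-variance comparison
retains the task) followed by SVM stacking of the retained tasks'
probabilities.

## Evaluation protocol

Folds are stratified at the subject level — per-fold class counts differ by
at most one from exact proportionality — which is what reproduces the
printed 310+226 → six folds of 54 (31+23) and four of 53 (31+22)
composition; a plain shuffled k-fold would not guarantee it. Each repetition
reshuffles with seed base+r; within every fold the entire two-stage ensemble
is refit from scratch. A repetition's score is the unweighted mean of its k
fold scores and the final score the mean over repetitions (fold-size
weighting would change results by <0.2% at these sizes). Metrics come from
the fold confusion matrix with depressed positive; a 0/0 ratio is reported
as 0 and flagged. The published-scale protocol is 100 repetitions; the
desk-scale default is 5.

## Synthetic corpora

The generator is a harmonic-plus-noise source-filter model: an AR(1) F0
track (ρ = 0.97 at 100 Hz, stationary sd = the speaker's f0_sd) drives a
12-harmonic source with 1/k rolloff through three two-pole resonators
(500/1500/2500 Hz × per-speaker shifts), with syllabic raised-cosine
amplitude modulation, pauses inserted per syllable gap with probability
pause_prob, and a −70 dB noise floor. It is deliberately unintelligible:
only group-discriminative prosodic structure matters downstream.

Speaker profiles are drawn from population distributions chosen to sit in
the middle of conversational-speech ranges: f0_mean ~ N(160, 40) Hz (mixed
sexes), f0_sd ~ N(25, 8) Hz, rate ~ N(4.0, 0.7) syll/s,
pause_prob ~ N(0.15, 0.07), formant shifts ~ N(1, 0.05). The depressed group
shifts three markers simultaneously — f0_sd down, pause_prob up, rate down —
each by `effect_size` population SDs, one knob for the whole separation.
Task identity modulates pause probability and tempo (and interview-style
tasks run ~45% longer than picture-description tasks), so the nine tasks are
non-identically informative. Corpus generation retries an utterance (derived
seed) until at least 0.5 s is voiced, mirroring the retention of only
VAD-surviving recordings in clinical collection.

What the generator does **not** emulate: lexical content, channel/device
variation, gender and age covariates, comorbid affect, or any fitted
relationship between marker magnitudes and clinical severity — the effect
directions follow the paralinguistic literature qualitatively. Passing the
synthetic power test therefore shows the pipeline detects prosodic group
structure of the stated size through real rendered audio; it says nothing
about accuracy on clinical recordings.

## Desk-scale study sizes

Tests and the acceptance script run: a 24-speaker × 8-utterance pre-training
corpus (~3 s utterances), the tiny TDNN profile, a 60+60-subject cohort with
nine tasks, and 5 repetitions of stratified 10-fold CV, at effect sizes 2
(power: accuracy ≈ 0.9) and 0 (null: accuracy within the 95% binomial band
of 0.5 for n = 120). These sizes were chosen once as the smallest study a
reviewer would find convincing; cross-seed variation of the power estimate
is a few points, dominated by the cohort draw rather than extractor training.

## Known limitations

- PLP uses triangular Bark masks rather than Hermansky's exact trapezoids;
  the cepstra are well-behaved but not toolkit-bit-identical.
- No batch normalization or margin losses in the encoders; at published
  scale (902 speakers) the optimization would likely need both.
- SVM probability calibration uses the library's internal five-fold Platt
  scaling, which adds its own randomness; it is seeded, but calibrated
  probabilities at desk sample sizes are noisy.
- The i-vector EM treats utterances independently (no minimum-divergence
  re-estimation step); recovery tests show this is sufficient at desk scale.
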