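# Methods

## Scope and model

`atlaspd` implements a complete, seeded testbed for three-class staging of
early Parkinson's disease (healthy controls, Hoehn–Yahr stage 1, stage 2)
from block-design prefrontal fNIRS.  Because no clinical recordings ship
with the package, a synthetic generator provides cohorts with the
statistical structure the analysis assumes; everything downstream — the
preprocessing chain, the hybrid classifier, the comparators, the robustness
and interpretability layers, and the power/effect-size utilities — operates
identically on simulated or real dual-wavelength data.

## Block design and montage

A session is 840 s at a configurable sampling rate (100 Hz reference): a
10 s pre-task baseline followed by cycles of 30 s rest, 30 s task, 50 s
rest.  The total duration is authoritative; the default of 7 cycles leaves
60 s of trailing rest (the cycle count is a free parameter of the protocol,
and any decomposition of the 840 s is admissible).  The montage is 22
channels at 3 cm source–detector separation partitioned into six regions:
L-FPC {CH01, CH05, CH06, CH10}, R-FPC {CH04, CH08, CH09, CH13}, mFPC
{CH02, CH03, CH07, CH11, CH12, CH16}, L-DLPFC {CH14, CH15, CH19}, R-DLPFC
{CH17, CH18, CH22}, BA8 {CH20, CH21}.

## Synthetic cohorts

Each subject's evoked HbO series is a boxcar task regressor convolved with
a double-gamma hemodynamic response function (main peak 5.5 s, undershoot
near 15 s, peak normalized to 1; the main gamma's shape parameter is
adjusted numerically so the realized argmax lands on the requested peak
time despite the undershoot subtraction).  The convolution is scaled by the
kernel sum so the injected amplitude is the plateau height in µM.

Class structure (`GroupEffectProfile`): amplitudes are per region and per
class, with a per-channel multiplicative variability draw.  Two presets
exist.  The `default` preset encodes moderate separation; `high_snr`
encodes the wide separation used by the learnability studies.  In both, the
stage-1 class hyper-activates frontal-polar cortex *and recruits DLPFC/BA8*
(extra active channels), and the stage-2 class is attenuated and delayed
(latency shifts 0 / 1.0 / 2.5–3.5 s).  This choice is deliberate: the
preprocessing chain standardizes every (subject, channel) series to unit
variance, which erases absolute amplitude scale, so a physiologically
plausible generator must carry class information in the recruitment
pattern, the response latency, and the per-channel signal-to-noise
fraction — all of which survive normalization.  `restricted_to(channels)`
confines the evoked signal to a channel subset (used by the
interpretability recovery study); `scaled(f)` multiplies all amplitudes
(the gait-imagery task variant uses 0.6, an assumption reflecting the
weaker pilot-task activation, not a measured value).

Noise (`NoiseProfile`): cardiac (1.1 Hz), respiratory (0.25 Hz) and Mayer
(0.1 Hz) oscillations with channel-specific phases — modeled as blood-volume
waves moving HbO and HbR in the same direction, which is what the scalp
coupling index keys on — plus random-walk drift, white noise, exponential-
decay motion transients added in intensity space, optional decoupled "bad"
channels (near-flat, independent noise per wavelength), and missing samples.
HbR is −1/3 of the evoked HbO response (typical inverted response;
configurable).  Defaults are in µM and chosen at the scale of task-evoked
prefrontal responses (evoked 0.1–0.9 µM against ~0.03–0.05 µM white noise).

Forward optics invert exactly what the preprocessing chain solves: the
modified Beer–Lambert law with a declared extinction table at 695/830 nm,
DPF 6.0, 3 cm separation, baseline intensity 1.0 (arbitrary units; only
ratios matter after OD conversion).

What the generator does **not** emulate: superficial/systemic physiology
distinct from cortex (no short-separation channels), optode-position
errors, subject-specific anatomy, task-performance coupling, or
non-stationary artifact statistics.  Passing tests therefore demonstrate
the pipeline's correctness and the architecture's learnability under the
stated assumptions — not clinical performance on real recordings.

## Preprocessing chain

Per subject, in order: intensity → optical density (reference = pre-task
window; non-positive samples flagged missing, bridged by interpolation for
the filters and re-flagged for imputation) → temporal-derivative
distribution repair → hybrid spline/wavelet repair on detected motion
segments → channel quality gating → zero-phase 4th-order Butterworth
low-pass at 0.1 Hz (padding scaled to the filter time constant) → modified
Beer–Lambert inversion → pre-task-mean baseline correction →
Savitzky–Golay smoothing (order 3, window 5) → optional decimation →
IQR winsorization (k = 1.5, per channel across time) → multiple imputation
(m = 5 chained-equation draws, averaged; channels over 50 % missing are
excluded instead) → per-(subject, channel) Z-scoring (constant channels are
zeroed and flagged, never divided by zero).  Excluded channels are refilled
with the cross-subject channel mean after normalization so the model input
width stays fixed at 22; the exclusion mask rides on the tensor.

TDDR interpretation: the canonical algorithm iteratively Tukey-reweights
the centered temporal derivative.  The two exposed parameters do not map
onto the canonical form, so they are implemented as (a) `sd_threshold` —
derivative samples beyond that many robust standard deviations are
artifacts and receive the fully reweighted derivative, and (b)
`amplification` — the fraction of the robust correction applied to
*non-artifact* samples (0 = untouched, 1 = full correction).  A linear ramp
passes through unchanged; a 10-sd spike is suppressed below 20 % residual;
a second application changes the output by under 1 % of the first-pass
correction.

Quality gating: the scalp coupling index is the zero-lag Pearson
correlation of the two band-passed (0.5–2.5 Hz) wavelength series
(degenerate series score 0; the score is NaN/not-applied when the cardiac
band lies above Nyquist, as in 1 Hz simulations).  The signal quality index
is a composite 1–5 rating from cardiac-band spectral prominence, flatline
fraction, and derivative-spike rate, each monotone, calibrated so clean
synthetic channels exceed 2.5 and flatlined channels fall below it (the
published scale's exact recipe is not reproduced anywhere accessible, so
this is a declared construction with the stated thresholds SQI < 2.5,
SCI < 0.5).

Sequence length: attention over the native 84 000-step series is
infeasible, so the chain decimates after the 0.1 Hz low-pass (Nyquist-safe)
to a configurable rate, 1 Hz by default (840 steps).

## Classifiers and training

The networks run on a small reverse-mode autograd core written on numpy
(float32), with fused layer-norm, batch-norm, dropout, softmax
cross-entropy and LSTM ops whose hand-derived backward passes are
gradient-checked against central finite differences in the test suite.

ATLAS-PD: linear projection 22 → d_model, batch normalization (placed
after the projection — the least intrusive reading of the regularization
recipe), sinusoidal positional encoding, post-norm Transformer encoder
layers (feed-forward width 4·d_model), one LSTM layer (width = d_model by
default) read out at its last hidden state, dense softmax head.  Plain
LSTM comparator: two stacked layers (128, 64) and a dense head.  Reference
hyperparameters: d_model 128, 4 heads, 2 layers, lr 8e-4 (hybrid) / 2e-3
(LSTM), dropout [0.3, 0.4], 120 epochs, L2 λ = 0.001, Adam, batch 16 —
optimizer and batch size are conventional defaults, not reported values.

Training protocol: cross-entropy + L2 on weights, early stopping with
patience 20 on validation loss, checkpoint at best validation accuracy
(ties broken by lower validation loss), all randomness from two named
seeds (data order: 42; initialization and dropout: 123).  Two optional
training augmentations address the small-cohort regime: random
contiguous-crop training (`crop_len`; the block structure repeats every
110 s cycle, so crops preserve the class signal while multiplying the
effective training set — prediction then averages class probabilities over
evenly spaced windows of the same length) and Gaussian input noise
(`augment_noise_sd`).  Both default to off.

Classical comparators consume engineered features because they cannot
ingest channels × time series: per channel {task-block mean, rest mean,
task−rest difference, sd, slope} → 110 features (a "flatten" mode also
exists).  Features are standardized inside each fit (no leakage).  Fixed
settings: SVM C 0.8/RBF with pairwise-coupled probabilities, RF 80/8/8,
k-NN 7/distance/kd-tree, MLP (80, 40)/α 0.02/180 iterations.

Hyperparameter search: Gaussian-process surrogate (Matérn 5/2 + white
noise) with Expected Improvement over layers [1, 5], heads [1, 12],
log-lr [1e-5, 1e-2], width [64, 512], dropout [0.1, 0.6]; inadmissible
width/head combinations are rejection-sampled; random-search fallback if
the GP fit fails; the per-candidate score is mean stratified 5-fold CV
validation accuracy.

## Evaluation

Stratified 70/15/15 split by per-class largest-remainder rounding (ties
favor earlier splits), so a balanced 240-subject cohort yields 168/36/36
and the combined train+validation pool is 204.  Metrics: confusion-matrix
accuracy/precision/recall/F1, per-class sensitivity/specificity, one-vs-rest
ROC AUC per class and their unweighted (macro) mean, percentile-bootstrap
95 % CIs over test resamples (1000 draws).  McNemar's test uses the
continuity-corrected χ² = (|b−c|−1)²/(b+c) with an exact binomial p-value
when b+c < 25.  Noise robustness adds N(0, σ²) to the normalized test
tensor over σ ∈ {0, 0.1, …, 0.5} (σ = 0 is evaluated without a draw, so it
reproduces the clean accuracy exactly), averaging 20 draws per positive σ;
both accuracy and macro AUC are reported per σ since either reading of the
protocol is defensible.  AUC_robustness is the trapezoidal area of accuracy
over σ divided by the σ range (a constant perfect classifier scores 1) —
the normalization is this package's convention, as the quantity is named
but not defined by a formula anywhere.

Permutation importance permutes one channel's whole series across subjects
(breaking its subject–label association while preserving its marginal),
repeats 10 times, takes the mean accuracy drop, min-max normalizes to
[0, 1] (an all-equal degenerate case returns zeros with a flag), ranks
descending with stable channel-id tie-breaks, and averages normalized
scores within anatomical regions.  The within-subject time-shuffle
alternative was considered and rejected because it also destroys temporal
structure unrelated to the channel's identity.  t-SNE embeds the
penultimate-layer activations (perplexity 30/50, 2-D/3-D) with a fixed
seed.  Encoder attention maps averaged over heads are exportable and
explicitly exploratory.

Power utilities use the noncentral F distribution with df (k−1, N−k) and
noncentrality λ = f²·N; the sample-size search returns the smallest total
N (stepping by 1) whose power reaches the target, which gives 111 for
f = 0.30, α = 0.05, power 0.80, k = 3.  Cohen's d uses the pooled standard
deviation; f = √(η²/(1−η²)).

## Problem sizes used in tests

The study conditions (100 Hz, 840 s, 22 channels, 80 subjects per class)
are the generator defaults.  The test and acceptance suites simulate at
10 Hz (all physiological bands remain below Nyquist) and decimate to 1 Hz,
with 60-subject cohorts and a width-32 / 2-head / 1-layer model trained on
110-step crops — sizes chosen so every property is exercised end to end on
a single CPU.  The spec-level invariants (bit-determinism, conservation of
injected amplitudes through the chain, forward/inverse consistency,
learnability, chance control under label shuffling, importance recovery)
are independent of these sizes.

## Known limitations

- The SQI recipe is a calibrated construction, not a reproduction of the
  original scale.
- The TDDR parameter mapping is an interpretation (documented above).
- Multiple imputation uses scikit-learn's chained-equations imputer with
  posterior sampling rather than a bespoke multilevel model.
- The generator's class structure is an idealization; accuracy numbers on
  synthetic cohorts say nothing quantitative about clinical data.
- Attention-map export is exploratory and carries no tested semantics.
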