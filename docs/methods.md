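# Methods

## Problem and model

`eegfuse` classifies three emotion states (boredom/negative, neutral,
engagement/positive) from multi-channel scalp EEG. The method rests on two
observations from the EEG emotion literature: class information is
concentrated in specific frequency bands (especially β 13–30 Hz and γ
31–50 Hz) and in temporal-lobe electrodes, so a classifier should look at
*band-resolved* signals from a *selected electrode subset* rather than the
raw full montage.

The pipeline is:

1. **Band division.** The continuous recording is filtered into the five
   canonical bands δ [1, 4], θ [4, 7], α [8, 13], β [13, 30] and
   γ [31, 50] Hz with order-4 Butterworth band-pass filters (the printed
   gaps 7–8 Hz and 30–31 Hz are left unassigned). Filters are realized as
   cascaded second-order sections and applied forward–backward
   (zero-phase). Zero-phase filtering keeps all five band signals
   time-aligned with each other and with the window grid; the price is
   that the *effective* magnitude response is the square of the order-4
   response (≈ doubled attenuation), which we consider harmless here
   since only relative band content matters downstream.
2. **Normalization.** Each band/channel series is z-scored with
   *population* (1/N) statistics computed per **subject** — pooled over
   all of that subject's recordings — then windows are cut. The scope
   matters: each recording carries a single label, so per-recording
   statistics would erase exactly the class-conditional band-power
   differences the classifier needs; subject-pooled statistics remove
   between-subject scale while preserving within-subject contrasts.
   `recording` and `segment` scopes are available via
   `preprocess_dataset(stats_scope=...)` for comparison.
3. **Windowing.** A sliding window of 10 s with a 2 s step, measured in
   samples (`round(window_s * fs)`); trailing partial windows are
   dropped. A 10 s window is 2000 samples at 200 Hz and 1280 at 128 Hz.
4. **Channel combination.** Named electrode subsets over the temporal
   regions: C1 (FT7, FT8, T7, T8, TP7, TP8), C2 (adds P7/P8, C5/C6,
   CP5/CP6), C3 (T7, P7, CP5, T8, P8, CP6) or `All` (montage order).
   Label matching is case-insensitive and whitespace-stripped.
5. **Backbone** (one branch per selected band, independent weights):
   Conv(32, kernel 5, stride 2, same) → ReLU → Conv(64, kernel 5,
   stride 2, valid) → ReLU → AvgPool(2) → BatchNorm → channel dropout.
   For a 2000-sample window the temporal lengths are 2000 → 1000 → 498 →
   249 with 64 feature maps; for 1280 they are 640 → 318 → 159.
6. **Fusion** of the per-band feature maps F_k (time × 64):
   - `add`: Σ_k F_k; `mult`: ∏_k F_k (element-wise);
   - `attention`: v_k = time-average of F_k; gate
     Weight_k = σ(q_kᵀ v_k) ∈ (0, 1) with a learnable per-band query
     q_k; fused F′ = Σ_k Weight_k · F_k.
7. **Classifier:** Conv(128, valid) → ReLU → Conv(128, same) → ReLU →
   AvgPool(2) → BatchNorm → Dropout → Conv(256, valid) → ReLU →
   Conv(256, same) → ReLU → GlobalAvgPool → Dropout → Dense softmax over
   3 classes. For a (249, 64) input the lengths run 245 → 245 → 122 →
   118 → 118 → 256 → 3.

### Architectural choices where the design was open

- **Kernel sizes** are 5 everywhere: this is the unique single choice that
  reproduces every published stage length above (2000→1000 same-pad
  stride 2; 1000→498 valid stride 2; 249→245 valid stride 1; 122→118
  valid stride 1), with the second convolution of each classifier pair
  'same'-padded to preserve length.
- **Classifier strides** are 1. A stride of 2 is arithmetically
  incompatible with the stage lengths the architecture is defined by
  (249 → 245 is impossible at stride 2), so the printed output shapes
  win.
- **Attention reading.** The gate is a *scalar per band per sample*,
  computed from the band's time-pooled feature vector against a
  *per-band* query, and gates multiply their own band's feature map
  before summation. This keeps the fused map the same shape as each
  branch output, which the classifier input requires. The alternative
  literal reading — gating the element-wise *product* of all selected
  bands with a single query — is implemented as fusion mode
  `attention_prod` for comparison.
- **Queries initialize to zero**, so every gate starts at the neutral
  value σ(0) = 0.5 and training begins from an unweighted average;
  conv/dense weights use uniform Glorot (fan-in + fan-out) initialization
  from a seeded generator.
- **No weight sharing across band branches**: the backbones share
  architecture only.
- **Dropout rates** (unstated upstream): 0.2 channel-wise in the
  backbone, 0.5 in the classifier; both configurable.
- **BatchNorm** uses eps 1e-3 and running-statistics momentum 0.9. The
  momentum is deliberately lower than the common 0.99 default: at
  desk-scale (≈ 4 batches per epoch) a 0.99 average needs tens of epochs
  before evaluation-mode statistics reflect the data, which makes early
  validation losses meaningless. With 0.9 the statistics settle within
  ~2–3 epochs.

The network, its gradients, and the optimizer are implemented directly
in numpy (convolutions as im2col matrix products). Every layer's
analytic backward pass is verified against central finite differences in
float64 by the test suite.

## Training protocol

Adam (β₁ 0.9, β₂ 0.999, ε 1e-7) at learning rate 0.001 with inverse-time
decay `lr_t = lr / (1 + 1e-5 · t)` per optimizer step; categorical
cross-entropy loss. Batch size 64, at most 100 epochs, early stopping on
validation loss with patience 10 and best-epoch weight restore, and a
`min_epochs` floor of 10 before early stopping may engage (see BatchNorm
note above — evaluation-mode loss is uninformative until the running
statistics settle, and stopping inside that window leaves the model
untrained). Batch size, epoch budget, patience and the floor are
desk-scale choices, recorded in every run manifest.

Cross-validation is stratified 5-fold at the segment level (8:2
train/test per fold), reported as mean accuracy and the standard
deviation over fold accuracies ("ACC/STD", population SD). Segment-level
folding lets overlapping windows from one recording land on both sides
of a split; this mirrors the protocol the architecture was designed
under but is optimistic about generalization. The effect is directly
measurable here: on *null* synthetic data with no class effect at all,
segment-level 5-fold CV sits around 40% (recording-specific noise
texture identifies the recording, and each recording has one label),
while the recording-grouped mode sits at chance. Two leakage-aware
alternatives are provided: `grouped` (StratifiedGroupKFold by source
recording — all windows of a recording stay on one side of every split)
and `per_subject` (one model per subject, per-subject means aggregated).
The statistical invariant tests use grouped splits for exactly this
reason. Fold seeds derive from the config seed, and two runs with the
same seed on the same thread configuration are bit-identical.

## Synthetic data

The generator emulates band-limited oscillatory EEG: per channel, a
unit-variance pink-noise (1/f) background (spectral shaping of seeded
random phases) plus one random-phase sinusoid bank per canonical band
(8 sinusoids drawn uniformly inside the band, scaled to unit variance).
Class effects multiply one band's component amplitude on a designated
channel subset, so a multiplier m yields an m² band-power ratio on those
channels before the background dilutes it. Defaults: 32-electrode 10–20
montage containing all C1/C2/C3 electrodes, 128 Hz, 30 s recordings
(11 windows each), 2 subjects × 4 recordings per class per subject
(264 segments), background and band-component SD 0.7, ±5% per-recording
amplitude jitter, and a γ-band-only graded effect on the C1 electrodes:
multiplier 1.0 (boredom), 1.5 (neutral), 2.0 (engagement). Amplitudes
are in arbitrary units since normalization removes scale.

What passing tests on this data do **not** show: robustness to eye-blink
and muscle artifacts, volume conduction, non-stationarity, electrode
drift, or between-subject variability in effect topography — none of
which are simulated. The synthetic benchmark validates the *mechanics*
(the pipeline recovers class-conditional band-power structure, attends
to the informative band, and stays at chance when labels are shuffled),
not clinical-grade performance.

## Numerical choices and degenerate inputs

- Filters reject pass-bands at or above Nyquist (γ needs fs > 100 Hz);
  `decompose_bands` raises by default and omits γ only on request.
- Zero-variance channels raise a `FlatChannelError` naming the channel.
- Non-finite samples are rejected before filtering.
- Windows shorter than one analysis window raise rather than return an
  empty list.
- Softmax ties break toward the lowest class index via `argmax`.
- Probabilities are computed in float32; checkpoints store exact arrays
  and reloading reproduces evaluation bit-for-bit.
- Average pooling drops a trailing odd sample (245 → 122), matching the
  published stage lengths.

## Problem sizes used in tests and the acceptance script

Shape/bookkeeping/filter checks are instantaneous. The statistical
checks run on the generator defaults (264 segments, C1, bands δ/β/γ):
chance-level control trains 5 folds × 6 epochs on label-shuffled data;
separability recovery runs 5-fold CV at max 15 epochs (min 12);
attention-gate ranking trains 10 seeded models for 6 epochs each. These
budgets were fixed from pilot runs showing convergence well inside them
(validation accuracy saturates around epoch 7–9 on this data).

## Known limitations

- The numpy network is CPU-only and desk-scale; it is not intended for
  training on full-scale 62-channel corpora.
- `per_subject` cross-validation averages subject-level means; with very
  few subjects its STD is over a handful of values.
- The EDF reader trusts header sampling rates and labels; no artifact
  removal, re-referencing, or montage interpolation is performed
  (upstream cleaning is assumed).
- Learning-rate "decay" is interpreted as inverse-time per-step decay;
  set `decay=0` for a constant rate.
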