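# Methods

`voiceimu` implements a complete multimodal classification pipeline for
Parkinson's disease (PD) vs. healthy control (HC) discrimination from
synchronized speech and head-worn inertial (IMU) recordings: a synthetic
cohort generator, signal preprocessing and temporal alignment, five fusion
architectures on a matched recurrent backbone, nested subject-grouped
cross-validation with probability calibration, and pooled/per-task
statistical reporting.

## Synthetic cohort

Real recordings of this kind are clinical data and not freely
distributable, so the package ships a generator that emulates the
statistical structure the analysis relies on. Each participant contributes
task-level episodes: a speech waveform, a tri-axial accelerometer stream
(~1.1 kHz) and a tri-axial gyroscope stream (~3.8 kHz), referenced from a
manifest with participant/group/task/session metadata.

**Speech model.** A glottal-like impulse train follows an F0 contour
(mean `f0_mean`, slow random walk with SD `f0_sd`), shaped by three fixed
second-order formant resonators (500/1500/2500 Hz). The amplitude envelope
is the product of a syllabic modulation (`syllable_rate`, depth
`intensity_mod_depth`; rate 0 for the sustained vowel task) and a slower
amplitude tremor (`amp_tremor_freq` in 4–7 Hz, depth `amp_tremor_depth`).
Gaussian noise is added at `noise_snr_db` and the waveform is
peak-normalized. This is deliberately not phonetically realistic speech
(no formant dynamics or phonemic content); it reproduces the *markers*
that matter for the classification problem.

**IMU model.** Each axis is linear low-frequency drift + white noise + a
tremor sinusoid at `tremor_freq` ∈ [3, 7] Hz with variance `tremor_power`
and random phase. Because the pipeline z-scores each channel per episode,
the group signal is carried by the tremor-to-noise variance ratio, so
`noise_sd` is held identical across groups.

**Group effect model.** Baseline parameters are drawn identically for both
groups (HC values: `f0_sd` ~ U(8, 15) Hz, modulation depth ~ U(0.35, 0.6),
amplitude tremor depth ~ U(0, 0.05), SNR ~ U(15, 25) dB, baseline tremor
power 0.02). PD episodes apply shifts scaled by per-task effect magnitudes:

- `f0_sd` ×= (1 − 0.6·audio_effect)  — monopitch
- `intensity_mod_depth` ×= (1 − 0.5·audio_effect) — monoloudness
- `amp_tremor_depth` += 0.2·audio_effect — voice tremor
- `noise_snr_db` −= 8·audio_effect — breathiness / reduced
  harmonics-to-noise ratio
- `tremor_power` += 0.5·imu_effect·U(0.5, 1.5) — head tremor band power

With all effects at zero, the two groups are statistically
indistinguishable by construction (verified by two-sample KS tests in the
suite). Defaults put a strong effect on the audio channel of every task
and none on the IMU channel; an "IMU-informative" preset enables
`imu_effect = 1` on the movement-engaging tasks T03 (daily monologue) and
T06 (sustained vowel). These magnitudes were chosen once to reproduce the
qualitative modality hierarchy (audio strong, IMU near chance alone,
fusion helped where the IMU carries signal) — not any particular absolute
accuracy. The passing of the pattern tests shows the pipeline recovers
structure that is present; it says nothing about effect sizes in real
cohorts.

Cosmetic covariates (age uniform 55–75, balanced sex) are attached but
carry no signal. Episodes can be written to disk as WAV (float32 or PCM16)
plus IMU CSVs in two timestamp dialects — float seconds or integer 100 ns
"ticks" — to exercise the heuristic parser; or consumed in memory
(identical signals, same per-episode generator seeds).

## Preprocessing and alignment

- Audio loaded at 16 kHz (polyphase resampling with built-in anti-aliasing
  low-pass), averaged to mono, peak-normalized (all-zero input passes
  through).
- Log-mel front end: centered power STFT, NFFT 1024, hop 320 (20 ms), Hann
  window, 56 Slaney-style area-normalized mel filters over 0–8 kHz,
  natural log with a 1e-10 floor. The frame count is truncated to
  ⌊n/hop⌋ so a 15 s crop yields exactly 750 frames, each stamped at
  k·hop/rate. Zero padding is used at the signal edges. The filterbank
  convention, window and centering are choices the front end pins down
  explicitly; they follow the dominant open-source convention.
- IMU CSVs are parsed heuristically: the first time-like column
  ({time, timestamp, ticks, t}, case-insensitive) is the time base (ticks
  divided by 1e7), the first three remaining numeric columns are x/y/z,
  missing samples are forward- then back-filled, and time is re-based to
  start at zero.
- Accelerometer and gyroscope are independently linearly interpolated onto
  a uniform 100 Hz grid and truncated to the common length, giving a
  6-channel stream (ACC first). Each channel is median-centered and scaled
  by its SD (1e-6 floor), computed over the whole episode so training and
  test crops of one episode share the same scaling.
- For a model input, the 6-channel stream is linearly interpolated onto
  the mel-frame timestamps (edge values clamped), so both modalities share
  one temporal index T. Windows of 15 s are cropped from the overlap
  D = min(audio duration, IMU duration): a random start in [0, D − 15] in
  training, K = 3 random crops at test time (all identical when D ≤ 15 s).

## Architectures

All five variants share: encoders to a common width H = 96 (audio: two
length-preserving kernel-5 temporal convolutions 56→96→96 with ReLU; IMU:
per-timestep MLP 6→96→96, Linear–ReLU–Linear), sinusoidal positional
encoding added after each encoder, a 1-layer bidirectional GRU with 128
units per direction, temporal mean pooling to a 256-vector, and a
256→128→1 head with ReLU and dropout 0.20. The backbone and head are
matched across variants so capacity depends only on the fused width D.

- `audio_only` / `imu_only`: Z is the single encoder output (D = 96).
- `early_concat`: zₜ = [aₜ ∥ iₜ] (D = 192).
- `gated_early`: a gate MLP 192→96→192 (ReLU hidden with dropout 0.10,
  sigmoid output) produces gₜ ∈ (0,1)^192 and ẑₜ = gₜ ⊙ zₜ.
- `mid_xattn`: audio queries a learned linear projection φ of the encoded
  IMU sequence through 4-head attention (d_head = 24, attention dropout
  0.10); the output is added residually to the audio sequence and
  layer-normalized (post-norm), D = 96.

The networks are implemented in NumPy with hand-written backpropagation
(dense, temporal convolution, GRU, multi-head attention, layer norm,
dropout), all verified against central finite differences. Weight
initialization follows fan-based uniform schemes seeded from the run seed.
φ is a single linear map, the minimal parameterization consistent with the
design; the gate's hidden activation is ReLU, matching every other MLP in
the model.

## Training, validation and calibration

Optimization is class-weighted binary cross-entropy (weights inverse to
training class frequency, normalized to mean 1) with AdamW (lr 1e-3,
weight decay 1e-2, β = (0.9, 0.999), ε = 1e-8), batch size 32, gradient
norm clipped at 1.0, FP32, constant learning rate, at most 50 epochs.
One random crop per episode is resampled each epoch. Validation AUC is
computed each epoch on raw (uncalibrated) probabilities from one fixed
crop per validation episode; early stopping monitors the mean of the last
three epochs' AUCs with patience 4 and restores the best-smoothed-AUC
weights.

The evaluation protocol is an outer 5-fold participant-grouped,
label-stratified split (greedy per-class round-robin deal, seeded) and,
within each training fold, 3 participant-grouped 70/30 train/validation
repetitions. Per repetition, temperature scaling is fitted on the
validation TTA logits by bounded scalar NLL minimization with guard-rails
T ∈ [0.300, 3.000], and the operating threshold t★ ∈ [0.200, 0.800] is the
smallest grid value (unique calibrated probabilities ∪ 0.01 steps)
maximizing validation F1. Validation sets smaller than 20, or single-class
sets, fall back to T = 1, t★ = 0.5; fallbacks and guard-rail clipping are
recorded as red flags. The three repetitions are ensembled by averaging
calibrated probabilities; the ensembled operating threshold is the mean of
the repetitions' t★ (the averaging rule for thresholds is a design choice,
logged per fold for audit). Held-out episodes are predicted with K = 3
TTA crops, logits averaged before calibration. Episodes lacking a modality
a variant needs are excluded from that variant (multimodal variants use
only tri-modal episodes). Train/validation/test participant disjointness
is asserted on every repetition.

All randomness (splits, initialization, crops, TTA) derives
deterministically from the experiment seed together with variant, scope,
fold and repetition indices; a rerun with the same seed reproduces the
prediction table byte for byte.

## Reporting

AUC is computed on calibrated probabilities (rank statistic, ties counted
half — identical to trapezoidal ROC integration); F1, accuracy, precision
and recall use each fold's ensembled threshold with PD as the positive
class. Fold scores are summarized as mean, sample SD and a Student-t 95%
CI. Per-task tables compute metrics within (method, task, fold) cells and
average over folds; single-class cells yield a missing AUC, excluded from
the mean with the exclusion count reported rather than imputed at 0.5.

Method-vs-baseline comparisons use the exact paired two-sided Wilcoxon
signed-rank test across folds: zero differences dropped, mean ranks for
ties, p by full enumeration of the 2^m sign assignments (with n = 5 folds
the two-sided floor is 2/32 = 0.0625). Holm adjustment defaults to the
full 12-comparison family (4 methods × 3 metrics) — with that family the
0.0625 floor maps to 0.75; a per-metric family mode is available behind a
flag. Zero-difference handling follows the classic (drop) convention
rather than the Pratt variant. Pooled ROC curves concatenate probabilities
across folds (labeled as such) rather than averaging per-fold curves.

## Problem sizes and numerical choices

The CPU-only implementation runs the full protocol at a reduced scale: the
standard synthetic cohort uses 16 PD + 16 HC participants over three tasks
(T03, T04, T06), one session each, episode durations 10–22 s, and the
scaled-down training regime (3 s crops, i.e. T = 150 frames, epoch cap 15).
These sizes are the package's own choices for the synthetic study; the
protocol itself (5 outer folds, 3 repetitions, calibration, TTA) is
unchanged, and the 15 s / 50-epoch configuration remains the default
`TrainConfig`.

Other numerical details: temperature fitted with tolerance 1e-4 and values
within 1e-3 of a bound snapped to it (flagged); smoothed-AUC improvements
require an excess above 1e-12 so bit-level noise does not reset patience;
a constant IMU channel normalizes to zeros via the SD floor; interpolation
beyond a stream's support clamps to edge values; all-zero audio is left
unnormalized.

## Known limitations

- The generator's speech is a schematic vowel-like source-filter signal;
  tasks differ only through syllable-rate profiles and effect magnitudes,
  not content. Results on it do not transfer quantitatively to clinical
  recordings.
- Session-level clinical covariates are cosmetic; severity is not modeled.
- No subject-level aggregation across tasks: each episode is classified
  independently, as in the evaluation design this package implements.
- The exact Wilcoxon enumeration is limited to 20 nonzero differences
  (fold-level use is n = 5).
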