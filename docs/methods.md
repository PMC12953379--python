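# Methods

This note documents the models, algorithms and design choices in
`cardiosleep`: what each stage of the pipeline computes, which parameters
matter, what the synthetic data do and do not emulate, and where the design
was genuinely open.

## Problem setting

Four-class sleep staging (WAKE, merged N1/N2 light sleep, N3 slow-wave
sleep, REM) from signals a chest-patch wearable can record at home:
single-lead ECG and three-axis accelerometry, both at 125 Hz. Sleep is
scored on 30-second epochs; a full recording window covers up to 10 h
(1,200 epochs). Cardiorespiratory staging exploits the coupling between
sleep state and the autonomic nervous system: heart rate, heart-rate
variability, respiratory rate and breathing regularity all vary with sleep
stage, and body movement concentrates in wake.

## Accelerometer-derived respiration (ACC-RESP)

A chest patch does not output a respiratory waveform. Breathing moves the
chest wall along a roughly fixed body axis, which appears in the device
frame as a small (~0.01 g) oscillation superimposed on the gravity vector.

Two extraction modes are implemented, sharing one windowing scheme
(30-second windows, 50% overlap, Hann-weighted overlap-add; per-window
principal axes sign-aligned with the previous window, the first window's
sign chosen so its largest-magnitude component is positive):

* **Gravity-plane (baseline)**: the gravity direction is estimated by
  low-pass filtering each axis (2nd-order Butterworth, 0.04 Hz cutoff,
  zero-phase) and renormalizing; the residual is band-passed to the
  breathing band (0.08–0.8 Hz, i.e. 4.8–48 breaths/min), projected onto
  the plane perpendicular to local gravity, and reduced per window to the
  first principal component of the 2-D in-plane covariance. This method is
  structurally blind to respiratory motion parallel to gravity — exactly
  the supine case when the chest moves anterior-posteriorly.
* **Orientation-robust**: all three axes are band-passed (the high-pass
  edge removes the quasi-static gravity component, replacing the geometric
  projection) and each window is reduced to its first 3-D principal axis.
  This recovers respiratory motion at any angle to gravity, mimicking what
  a thoracic impedance band measures, and is equivariant to any fixed
  rotation of the device frame (up to a global sign).

The output is resampled to the staging model's respiratory grid,
307,200 samples per 10 h (8.5333… Hz), by polyphase rational resampling
with the exact ratio 128/1875 relative to 125 Hz, so the sample grid is
bit-reproducible. Windows with rank-deficient covariance reuse the
previous window's axis and are logged. Interior gaps of at most 5 s are
linearly interpolated; longer gaps are zero-filled (nights with any gap
over 30 min are excluded upstream, see below).

Free parameters live in `ExtractionConfig`; the defaults above were fixed
once, from physiology (adult breathing rates) and the epoch timescale, and
are the values all tests use.

## Preprocessing and inclusion rules

Each night becomes a fixed-length model window: ECG polyphase-resampled to
1,228,800 samples per 10 h (34.1333… Hz; 1,024 samples per epoch) and
respiration to 307,200 (256 per epoch). Nights shorter than the window are
right-padded with zeros and PAD labels; longer nights keep their first
10 h (sleep onset matters for onset-latency metrics, and the window was
sized for whole nights). Per-night amplitude normalization is
median/interquartile-range with clipping at ±10 — robust to the heavy
tails and motion spikes of wearable ECG; a zero-IQR (constant) channel
normalizes to all zeros with a logged warning.

Quality screening: a night fails if any single contiguous missing-data run
in ECG or accelerometry exceeds 30 minutes (the rule is per gap, not
cumulative), or if its hypnogram is entirely ARTIFACT. A participant is
included only if at least 75% of their study nights pass. ARTIFACT and PAD
epochs are excluded from the training loss and from every agreement
metric; ARTIFACT epochs still count toward time in bed (the scorer deemed
them unscorable, not wake).

## Staging model

The network classifies all epochs of a window jointly:

| stage | operation | output (full scale) |
|---|---|---|
| signal encoder (ECG) | 8 residual blocks, features 16,16,32,32,64,64,128,128 | 4,800 × 256 |
| signal encoder (resp) | 6 residual blocks, features 16,32,64,64,128,128 | 4,800 × 256 |
| per-epoch fusion | reshape to 1,200 × 1,024; shared dense 1,024 → 128 | 1,200 × 128 |
| epoch mixer | sum modalities + sinusoidal positions; 2 transformer blocks | 1,200 × 128 |
| sequence mixer | 12 dilated conv layers, kernel 7, dilations (1…32)×2 | 1,200 × 128 |
| head | dense 128 → 4 per epoch | 1,200 × 4 |

Each residual block applies three kernel-3 convolutions with batch
normalization, a projection (1×1) skip when the channel count changes, a
ReLU after the join, and factor-2 max pooling — so 8 blocks divide the ECG
by 256 and 6 blocks divide respiration by 64, both landing on 4 frames per
epoch. Design points that were open and fixed here:

* The encoder ladders end at 128 channels but the fused representation is
  4 frames × 256 channels per epoch; a final width-256 1×1 convolution
  (with batch norm and ReLU) bridges the two.
* Transformer blocks are post-norm, 8 heads, feed-forward width 512
  (4× the model dimension), dropout 0.1, fixed sinusoidal positional
  encoding. Attention is full-sequence: every epoch attends to all 1,200.
* Modalities are fused by summation; a learned per-modality null vector
  stands in when a modality is absent, which is what makes the ECG-only
  variant a special case of the same network.
* The sequence mixer units are residual (`x + relu(conv(x))`); its
  receptive field is 1 + (7−1)·(1+2+4+8+16+32)·2 = 757 epochs, verified by
  an impulse-response test.
* The classification head's initial weights are scaled down so training
  starts near the uniform-prediction loss ln 4.

The implementation is numpy with hand-written backpropagation (layers in
`cardiosleep.nn`), verified against central finite differences to ~1e-9
relative error in float64. One forward/backward pass processes one night;
"batches" are formed by gradient accumulation. Batch normalization
therefore uses per-night (instance) statistics during training and running
averages in evaluation. A `no_grad` context drops backprop caches so
full-scale forward passes stay within a few hundred MB.

`reduced_config()` is the same topology at ~8× narrower widths with 6 ECG
blocks (256 samples per epoch, 8.53 Hz) and 4 respiration blocks (64 per
epoch, 2.13 Hz); it exists so training experiments complete on one CPU.

## Training

AdamW (decoupled weight decay, default coefficient 0.01) on cross-entropy
masked to scored epochs. Transfer-learning defaults follow the protocol
the package models: fixed learning rate 1e-5, batch size 16 nights,
validation after every training epoch, early stopping when validation loss
fails to improve strictly on its running minimum for 5 consecutive
evaluations, and reversion to the minimum-validation-loss weights. No
layers are frozen during fine-tuning. Leave-one-subject-out
cross-validation builds one split per participant; with 13 participants
each split trains on 10 and validates on 2 (generally
`max(2, ceil(remaining/6))` validation participants, drawn
deterministically from the split seed). Test participants never contribute
gradients, which the tests verify by construction and by a
gradient-equality audit.

## Synthetic cohorts

The generator produces the statistical structure the stager exploits,
not physiologically faithful signals:

* **Hypnograms**: a 4-state Markov chain on the 30-s grid with constant
  switching rate r = 0.05 (mean bout lengths 1/(r(1−π)) epochs) and
  stationary mix π = (12.1, 32.3, 35.6, 20.0)% for WAKE/N1N2/N3/REM —
  the label mix of a home-EEG insomnia cohort. Nights start with a
  geometric wake run with mean equal to the target sleep-onset latency
  (16.7 min). Two cycle modulations are superimposed: N3 entry decays by
  exp(−0.02·cycle) across 90-min cycles (front-loading, kept weak so the
  %N3 of a night is nearly independent of its length), and REM entry is
  scaled by 0.25 + 1.5·phase within each cycle (unit mean, so the long-run
  mix is preserved). Long nights are redrawn in the rare case no REM bout
  occurred. The empirical stage mix over 200 default nights stays within
  ±5 percentage points of the chain's eigen-stationary distribution.
* **ECG**: template beats (Gaussian R wave plus a low T wave) placed at
  simulated R-times. Only the inter-beat intervals carry stage
  information: per-epoch Gaussian RR around the stage mean
  (65/60/55/62 bpm for WAKE/N1N2/N3/REM) with stage SD (60/50/30/70 ms),
  plus a respiratory-sinus-arrhythmia term (20 ms) locked to the
  respiration phase. Beat morphology is deliberately crude.
* **Accelerometry**: a piecewise-constant unit gravity vector drawn from
  supine/lateral/prone orientations (small random tilt, exponential
  holding times, smooth 3-s transitions), plus sinusoid-like respiratory
  displacement (0.01 g) along a body-fixed axis at the stage's rate
  (14/15/13/16 breaths/min) with stage-dependent rate jitter (REM most
  irregular), plus wake-time motion bursts and sensor noise. The default
  respiratory axis is the anterior chest normal, so supine posture puts
  breathing parallel to gravity — the case that separates the two
  extraction modes.
* **Cohorts**: per participant, baseline time in bed ~461 min with
  between/within-participant variation; intervention night I1 removes a
  configurable amount of time in bed (default 120 min), relaxing linearly
  to zero at follow-up F1; the %N3 share of sleep drifts by a configurable
  slope (default −1 pp/night) across intervention nights, injected by
  rebuilding the transition matrix around a shifted stationary mix.

All stage-dependent defaults live in one editable file
(`src/cardiosleep/defaults.yaml`). Everything is reproducible bit-for-bit
from the seeds carried by the parameter objects.

What the generator does *not* emulate: realistic ECG morphology or noise
(electrode pops, muscle artifact), apnea/arousal events, inter-individual
physiology differences beyond the injected shifts, or scorer disagreement.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that the model can learn stage-dependent cardiorespiratory
structure — not that it reaches any particular accuracy on real wearable
recordings.

## Desk-scale experiment sizes

The learnability and transfer experiments (in `cardiosleep.experiments`)
use 2-h nights (240 epochs) on the reduced grid: a 12-participant × 5-night
cohort (40 training, 10 validation, 10 test nights), AdamW at 1e-3, batches
of 4 nights, up to 40 epochs with patience 20 (validation loss passes
through a long plateau before the stage-discriminative features emerge,
so short patience stops too early). A per-epoch logistic
regression on oracle spectral features reaches κ ≈ 0.9 on these cohorts,
confirming the reduced grids retain the stage information; the network
reaches κ well above the 0.3 chance-exceedance threshold within this
budget. Transfer experiments fine-tune that checkpoint on 7-participant × 3-night
cohorts whose physiology is shifted by +8 bpm heart rate and +3 breaths/min
(4 training / 1 validation / 2 test participants, learning rate 3e-4, up to
6 epochs, patience 3) and compare held-out κ before vs after fine-tuning
across seeds. The longitudinal %N3-slope recovery check regresses
cohort-mean %N3 over the intervention nights of a 150-participant cohort:
per-night %N3 has a standard deviation of several percentage points from
stage-bout noise alone, so the regression oracle needs that much
averaging to resolve a 1 pp/night trend. These sizes are the package's
standing experiment conditions; `scripts/acceptance.py` reruns them from
scratch.

## Numerical choices and degenerate inputs

* Exact rational resampling everywhere (`Fraction`-reduced polyphase), so
  grid lengths are deterministic: 1,228,800/1,200 = 1,024 ECG and
  307,200/1,200 = 256 respiratory samples per epoch, asserted in code.
* Cohen's κ: (p_o − p_e)/(1 − p_e) from row/column marginals; if chance
  agreement is 1, κ is defined as 1 when observed agreement is also 1 and
  an error otherwise. Accuracy ≥ κ bookkeeping (p_o = κ + p_e(1−κ)) is
  property-tested.
* Paired t-tests with zero-variance differences are reported as
  degenerate (p = 1 for identical conditions) rather than NaN.
* All-wake nights have undefined onset latency and stage percentages
  (returned as missing, not zero).
* PCA sign indeterminacy is resolved by continuity (see above); ties in
  max pooling resolve to the first maximum (numpy argmax semantics).

## Known limitations

* The orientation-robust extraction is specified here as 3-D band-pass plus
  windowed first-principal-axis projection — the minimal modification that
  removes the perpendicular-to-gravity assumption while keeping the
  windowed-PCA character of the baseline; other fusions (e.g. adaptive
  per-axis weighting) are possible and isolated behind `ExtractionConfig`.
* Batch statistics are per-night; large-batch batch-norm behavior is not
  reproduced.
* Time in bed is operationalized as the scored-window duration and onset
  latency from recording start, because a self-applied home device has no
  lights-off annotation; comparisons with polysomnography-derived tables
  should keep that in mind.
* The numpy implementation is single-threaded BLAS-bound; full-scale
  training (10-h windows at published widths) is out of its intended use,
  which is correctness, reduced-scale experiments, and inference.
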