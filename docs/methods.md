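# Methods

## Problem and model

`semgintent` classifies lower-limb motion intent from 8-channel surface
electromyography (sEMG) sampled at 1000 Hz.  Recordings are organized as
trials of roughly 1.5 min with a contiguous motion-event timeline over a
17-class locomotion vocabulary (sitting, standing, walking, stair and ramp
ascent/descent, turning, uneven terrain, and eight small/diagonal stepping
patterns).  Overlapping windows (W = 1200 ms, step S = 200 ms) are labeled
*predictively*: the label of a window starting at t is the event active at
t + W + P_label, where P_label (default 100 ms, swept 100–500 ms) is the
look-ahead interval.  This makes the task anticipation, not description.

The classifier is a two-branch encoder with a fusion stage:

- **Time–frequency branch.** Each window is mapped to a 30-scale complex
  Morlet scalogram (center frequencies log-spaced 450 → 20 Hz).  Three
  frequency-partitioned stages of [3×1 temporal convolution with one
  independent kernel per scale band → 4×1 average pooling] shrink time
  1200 → 299 → 74 → 18 while keeping bands independent; an aggregation
  convolution (30 → 16 channels, 3×1, followed by batch norm and
  Leaky-ReLU slope 0.01) mixes bands, and the (16 features × 16 steps × 8
  muscles) block is rearranged into a length-16 sequence of 128 features.
- **TCN.** Three temporal blocks (channels 128-256-128; two causal dilated
  convolutions each, kernel 3, dilations 1/2/4, batch norm + ReLU, residual
  connections with 1×1 width matching, left-pad-and-chomp causality).  The
  closed-form receptive field is 1 + Σ (k−1)d = 29 steps ≥ 16, so every
  output step can see the whole sequence.
- **Frequency branch.** The window's one-sided FFT magnitudes (601 bins ×
  8 channels) pass two shared 3×1 convolutions and 4×1 max pooling to
  (149 × 8), flattened to 1192 features.
- **IFIA fusion.** At the stage-2 insertion point (30 × 74 × 8) the module
  (i) gates each scalogram band with logistic(MLP(frequency features)) — a
  squeeze-style MLP with hidden width 1192/r, r = 4 by default; (ii)
  compresses the gated block over time into one global-modulation token per
  band/muscle; (iii) runs 2-head, d_model = 64 self-attention per muscle
  channel over the 74 original time-step tokens plus the compressed token
  (30-dim band vectors), adding the time-step outputs residually.  Three
  ablations drop one stage each; three conventional baselines fuse at the
  data level (spectrum linearly resampled to 1200 samples and appended as a
  31st input band), feature level (1192 frequency features concatenated into
  the decoder input) or decision level (a parallel frequency sub-network with
  its own TCN and head; probabilities averaged).
- **Decoder.** Flatten (2048) → batch norm → 32-dim embedding → Leaky-ReLU →
  dropout (p = 0.3) → linear scores over 17 classes.

Parameter accounting is part of the contract: with biases on every
convolution and affine batch norm everywhere, the baseline totals exactly
681,737 trainable scalars (1,848 branch + 609,664 TCN + 70,225 decoder) and
the data-level variant 681,797 (+60: one extra band's three conv taps and
biases plus one aggregation column).  The feature-/decision-level and IFIA
internals admit several parameterizations of similar size; this package
asserts their ordering (baseline ≤ data < feature < IFIA < decision), not
their absolute counts, and logs its own counts (722,273 / 1,054,131 /
3,804,898 for feature/IFIA/decision level).

## Training protocol

Per subject, trials are shuffled and split into five non-overlapping groups;
fold f tests on group f and splits the remaining trials 7:1 into train and a
rotating validation trial, realizing a 7:1:2 trial-level split with ten
trials.  No window of a test trial ever enters training (hash-guarded).
Optimization: softmax cross-entropy (log clamped at 1e-12), AdamW
(lr 0.003, β = (0.9, 0.999), weight decay 1e-4), batch 128, up to 100
epochs, ReduceLROnPlateau on validation loss (factor 0.5, patience 5),
early stopping (patience 15) with best-validation weight restoration.
Scheduler/early-stop constants are config-exposed: the protocol fixes the
policies, while their constants are tunable defaults.

### Numerical notes

- The network, backprop and optimizer are implemented directly in numpy
  (float32 forward/backward; float64 in gradient tests).  Every layer is
  verified against central finite differences, and each conv+pool stage is
  computed fused as a strided (k+p−1)-tap convolution that is exactly
  equivalent to conv-then-pool.
- **Batch-norm recalibration.**  With few mini-batches per epoch the usual
  running-statistics EMA (momentum 0.1) lags far behind the fast-moving
  activations of a deep stack, wrecking evaluation-mode predictions.  After
  every epoch the running statistics of all batch-norm layers are therefore
  replaced by exact aggregate statistics from a pass over (up to 768 windows
  of) the training set, with dropout disabled — the "precise BN" approach.
  Running statistics travel with checkpoints and with best-weight
  restoration.
- Percentiles use linear interpolation; events are half-open [start, end);
  a label time exactly at an interior event boundary takes the later event,
  and one exactly at the trial end uses the final event.
- Decision-level probabilities are equal-weight averages of the two
  sub-network softmaxes; its loss gradient flows through the average.

## Synthetic benchmark

No public sEMG recordings ship with the package.  The `synthetic` module
generates trials with the statistical structure the pipeline assumes: per
class and muscle channel, band-limited Gaussian noise (zero-phase 4th-order
Butterworth band-pass of white noise, unit carrier RMS) scaled by a
muscle-synergy gain pattern and modulated by a raised-cosine burst envelope
(duty cycle 0.5) at the gait cadence; static postures use a constant
envelope and low gains, so they sit below every dynamic class in RMS.
Subjects differ by multiplicative gain jitter U(0.8, 1.2) and ±10 Hz band
edge jitter.  Class recipes are fixed so that mean band-power signatures of
any two classes differ by at least 3× the within-class spread — the
regime in which the end-to-end experiment is well-posed.  The generator
emulates band structure, synergy patterns and cadence bursting; it does not
model motor units, electrode shift, impedance drift or fatigue, so passing
the end-to-end tests demonstrates that the pipeline learns separable
time–frequency structure, not that it reaches any particular accuracy on
real recordings.

### Problem sizes

The package's own test/benchmark sizes are chosen for a single-CPU numpy
budget:

- quick profile: 5 classes (sitting, standing, walking, ascending stairs,
  small steps in front), 1 subject × 10 trials × 20 s → 940 windows; the
  end-to-end check trains baseline and full-fusion models on fold 0 with a
  30-epoch cap (early-stop patience 5, scheduler patience 2) and requires
  ≥90% held-out accuracy; the six other variants run one epoch each to
  exercise the harness.
- prediction-time trend: the same classes at 10 s trials, P_label ∈
  {100, 500} ms, three training seeds, 8-epoch cap; the mean accuracy at
  500 ms must not exceed that at 100 ms by more than 2 points.
- full-length (90 s) trials and all 17 classes remain available through
  `DatasetConfig`/`generate_dataset` parameters.

## Design choices on genuinely open points

- CWT mother wavelet: complex Morlet, bandwidth 1.5, center frequency 1.0;
  30 scales log-spaced to span 20–450 Hz (descending).  The band count is
  fixed by the architecture; the wavelet and spacing are config-level
  choices.
- FFT uses a rectangular window and magnitudes (not powers); one-sided
  interior-bin doubling appears only in the Parseval test.
- Trial-level filtering and normalization precede segmentation: per-window
  filtering would corrupt edges, per-window percentiles would break
  amplitude comparability across windows.
- The 30 gates act on the scalogram bands (the channel axis at the fusion
  insertion point); attention weights are shared across the 8 muscle
  channels.
- Metrics are macro-averaged over classes present in the test labels;
  accuracy is the confusion-matrix trace over its total.

## Known limitations

- Training cost is CPU-bound numpy; wall-clock budgets dictate the quick
  profiles above, and the five-fold protocol over all variants is practical
  only at reduced sizes.
- The synthetic generator's class separability is by construction higher
  than real inter-class sEMG overlap; accuracies on it say nothing about
  accuracies on real recordings.
- Single-trial validation sets make the early-stopping signal noisy; the
  plateau scheduler partially compensates.
- Batch-norm recalibration adds one forward pass over the training set per
  epoch (~15–25% overhead at these sizes).
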