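# Methods

## Problem

Electrocardiograms recorded inside an MRI bore are distorted by the
magnetohydrodynamic (MHD) effect: blood flowing through the static field
induces a voltage that superimposes on the ECG, most prominently inflating
the T wave. At high field strength (7 T) the T wave can exceed the R peak
in amplitude, so amplitude-threshold QRS detectors lock onto the wrong
wave. Reliable R-peak times are nevertheless required for cardiac gating
and for in-bore patient monitoring.

This package casts R-peak detection as 1D semantic segmentation: a network
maps a 3-lead, 4-s ECG window sampled at 1024 Hz to a per-sample
probability of "inside an R-peak pulse". Labels are rectangular pulses of
height 1 and width 13 samples (~12.7 ms) centered on each annotated peak.
Peak locations are recovered from the predicted mask and scored as events.

## Model

The segmentation network is an encoder/decoder with three ingredients.

**Self-organizing operational (Self-ONN) layers.** Each "generative
neuron" replaces the convolutional inner product with a learnable
polynomial of order q:

    f(x) = b + w1*x + w2*x^2 + ... + wq*x^q,

lifted to multichannel cross-correlation by raising the input elementwise
to each power and correlating with a separate kernel bank per power; q = 1
recovers an ordinary convolution. We use q = 3 with tanh activations so
activations stay in (-1, 1). Bias is per output channel. Zero "same"
padding keeps lengths composable across the pyramid.

**Architecture.** Four encoder levels (16, 32, 64, 128 filters, kernel 11,
one operational block per level: Self-ONN, instance norm, tanh), each
followed by 2x max pooling; a 256-filter bottleneck; four decoder levels
mirroring the encoder with 2x linear upsampling. Every skip connection
passes through an attention gate: encoder and coarser decoder features are
projected to the encoder width with kernel-1 operational layers plus
instance norm, summed after upsampling the decoder branch, squashed with
tanh, reduced to one channel, instance-normed and passed through a sigmoid
to give a multiplicative mask in (0, 1) over the skip. The output head
fuses a feature pyramid: decoder maps of the three shallowest levels are
linearly interpolated to full length, concatenated (112 channels at the
default width), and reduced by a kernel-1 operational layer to one logit
channel. Ablation variants keep everything fixed and switch single
ingredients: `fpn_cnn` (q = 1, ReLU, plain skips) and `self_fpn`
(Self-ONN, plain skips).

**Training.** Binary cross-entropy on the sigmoid of the logits against
the pulse-train targets; Adam at a fixed 1e-3; batch 128 for 100 epochs at
full scale. Training windows use 75 % overlap as augmentation; validation
and test windows do not overlap. The per-epoch snapshot with the best
validation Dice score is kept. Splits are subject-wise (a subject's
records never straddle folds); the 5-fold protocol rotates 3 folds train /
1 validation / 1 test.

The class imbalance (~13 positive samples per ~800-sample beat period) is
left unweighted by default; `pos_weight` is exposed for harder regimes.

## Numerical backend

The network, its gradients and Adam are implemented on a small reverse-mode
autodiff engine over numpy arrays (`mhdnet.autodiff`). Convolutions pack
the input channels-last with per-window zero gaps so every kernel tap is a
contiguous view feeding one BLAS GEMM; the Self-ONN layer is fused (powers
are formed once on the packed copy). Gradient correctness is enforced by
finite-difference checks in the test suite, and the layer forward is
checked against an intentionally naive nested-loop oracle
(`selfonn_oracle`) that shares no numerics with the fast path. Weights use
a Glorot-style scale with the power-k bank damped by 1/k!, keeping early
activations in tanh's linear range; instance norm carries learnable affine
terms; upsampling is linear interpolation with edge clamping. All
computation is float32 except where tests require float64.

## Preprocessing

Records are cleaned before windowing: a 4th-order Butterworth bandpass
(0.05–100 Hz) followed by a Q = 30 IIR notch at 50 Hz, both applied
forward-backward so filtering is zero-phase and peak sample times are
preserved (verified to ±1 sample on a template beat). Each window is then
z-scored per channel; constant channels map to zeros. Amplitude
normalization matters because distortion severity differs strongly between
field strengths.

## Peak extraction and scoring

The segmentation model's contract ends at the mask, so mask-to-peak
conversion is this package's own: binarize at 0.5, drop runs shorter than 3 samples,
merge runs separated by less than 100 ms, and report the center of each
run's argmax plateau (for the rectangular labels this recovers the
annotated sample exactly). All four knobs are configurable.

Detection counts use greedy one-to-one matching in order of increasing
time error with tolerance floor(0.070 * fs) samples — 71 at 1024 Hz.
Segmentation quality is samplewise IoU and Dice on the binarized mask
against the label pulse train; two all-zero masks score 100 by convention,
and 0/0 event ratios report 0 with a warning. Counts are micro-aggregated
over all test records of a split before ratios are taken; cross-validation
averages per-fold metrics. Heart rate is 60 * fs / RR per consecutive beat
pair; agreement between estimated and reference HR uses only intervals
whose two bounding truth beats are both matched and adjacent (a missed
beat drops the two intervals it touches rather than corrupting them), and
is summarized by the Pearson correlation and the Bland–Altman bias ±
1.96 sd limits (sample sd, ddof = 1).

## Synthetic data

No public in-bore recordings ship with the package, so the generator
provides records with exactly known truth. A beat is a sum of Gaussian
bumps (P, Q, R, S, T) at fixed fractions of the RR interval; the artifact
channel holds a severity-scaled T-wave excess plus a bowed ST segment.
Severity presets: `3T-like` (severity 1: T comparable to R) and `7T-like`
(severity 2: T exceeds R, defeating naive amplitude detectors); `clean` is
severity 0 with no noise. Beat-to-beat RR is lognormal (sigma 0.05 around
the subject's rate); subjects draw resting HR from N(70, 6) bpm clipped to
[45, 120] and an amplitude factor from U(0.8, 1.2). Baseline wander (two
sub-0.5 Hz sinusoids, 0.25 amplitude), white noise (sd 0.03) and a 50 Hz
powerline tone (0.05) are added per lead; the cardiac and artifact sources
mix into three pseudo-leads with distinct polarities and weights. The true
R index is the center of the clean R bump and is invariant to severity and
noise by construction.

What the generator does not emulate: ectopy and arrhythmia, gradient-
switching and RF artifacts, electrode motion, inter-lead timing
differences, and real MHD morphology beyond T/ST inflation. Passing the
end-to-end tests therefore demonstrates that the pipeline is correctly
wired and trainable under severe T-dominance, not clinical-grade
performance on real in-bore data.

## Desk-scale experiment sizes

The full protocol (5-fold, 100 epochs, 23 + 5 subjects) is supported by the
code; the package's own end-to-end experiments run a reduced configuration
chosen to exercise every stage: 5 synthetic subjects with two 60-s records
each, one 3/1/1 subject split, a 2-level model with 8 base filters
(bottleneck 32, kernel 11, q = 3), 15 epochs at batch 32, learning rate
1e-3. On this configuration both ablation variants saturate detection
(test F1 at or near 100 %), so the segmentation-Dice ordering between the
attention model and the CNN baseline is within seed-to-seed noise at this
scale — the ablation separation reported at full scale should not be
expected from the desk-scale run.

## Known limitations

* The WFDB support is the subset this pipeline needs (format 16, MIT
  annotation streams); exotic header variants are rejected rather than
  guessed at.
* CPU-only; a full-scale 100-epoch training is feasible but slow
  (hours, not minutes).
* One model per field strength, mirroring the protocol; no cross-field
  generalization is attempted.
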