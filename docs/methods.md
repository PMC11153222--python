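# Methods

`ictus` implements a real-time seizure-onset detector for multichannel scalp
EEG: band-pass filtering, sliding-window short-time Fourier features, a
GoogLeNet-style inception CNN classifier, causal streaming detection, and
event-based evaluation. This note records the model, its parameters, the
numerical choices, and what the synthetic benchmark does and does not show.

## Signal model and preprocessing

Recordings are matrices of channels × samples in microvolts at 256 Hz, with
six fixed bipolar channels (P3-O1, FP2-F8, P8-O2, P7-T7, T7-FT9, FT10-T8)
selected for analysis; channel labels are compared after canonicalizing case
and dash styles, since the same montage appears with several dash variants in
the wild. All times are seconds from recording start and seizure intervals
are half-open `[onset, offset)`, which makes window-overlap arithmetic
unambiguous.

Raw EEG is band-passed 1–60 Hz with a Butterworth filter of total order 6
(three pole pairs per band edge, i.e. MATLAB's `butter(3, [lo hi])`), applied
forward and backward. Zero-phase filtering preserves the temporal position of
waveform features — the whole point of an onset-delay metric — at the cost of
squaring the magnitude response. The filter runs as second-order sections
with odd-reflection edge padding for numerical stability; recordings shorter
than the padding length are rejected rather than silently truncated. Two
consequences are worth knowing: the doubled band-edge skirts remove roughly
12% of broadband energy over the full 1–60 Hz span (the flat 5–45 Hz interior
is preserved within 5%), and forward–backward symmetry holds only beyond the
startup transient of the slow 1-Hz pole (about 2000 samples at 256 Hz).

## Features

The filtered recording is cut into 1.35-s windows (345 samples) sliding with
1-s overlap. The hop is computed in samples — 345 − 256 = 89 — because 0.35 s
is not an integer sample count at 256 Hz. Each window is transformed per
channel with an STFT using a 2-sample symmetric Hamming window (both taps
0.08), 1-sample hop, and a 128-point transform, giving 2-Hz bin spacing and
344 frames per window. Bins whose center frequency lies in the half-open band
[20, 60) Hz — exactly 20 bins — are kept; closed-interval selection would
give 21 and break the printed feature geometry. The six channel blocks are
stacked vertically into a 120 × 344 epoch (41,280 values). The other standard
rhythm bands (delta 1–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–60 Hz)
are selectable, changing the epoch height accordingly.

Values are log power: per frame, `|X_k|² / (nfft · Σw²)`, so the two-sided
bin sum equals the mean power of the windowed frame, reported as `10·log10`
dB with a floor at −120 dB. The floor guarantees finiteness for silent
windows; the log scale bounds the dynamic range the classifier sees. A scalar
zero-centering constant estimated from the training epochs is stored with the
model and subtracted at inference; the feature module itself emits raw dB.

Windows are labeled seizure-active when they overlap an annotated interval by
at least half the window length (configurable fraction). The batched feature
path computes per-channel frames once per recording and slices windows out of
the frame grid; every frame uses only samples inside its own window, so this
is exactly equal to per-window computation and keeps the stream causal.

## Classifier

The architecture is a 29-level GoogLeNet-style CNN sized for the 120 × 344
epoch: three stand-alone convolutions (5×3/64, 5×3/64, 1×1/192, valid
padding), five ceil-mode max-pooling levels (1×3 s1×3, 3×3 s2, 2×2 s2, 3×3
s2, 3×3 s2), nine inception blocks, a 7×7 average pooling, 40% dropout and a
2-way fully connected softmax head. Every convolution is followed by batch
normalization and ReLU. Padding is dictated by the shape arithmetic: valid
for the stem (344 → 342, 116 → 112), same inside inceptions (spatial size
preserved), ceil-mode pooling (112 → 56 with a 3×3 stride-2 pool requires
rounding up). Inception blocks use the canonical four-branch GoogLeNet
allocations (1×1; 1×1→3×3; 1×1→5×5; 3×3 pool→1×1), whose totals reproduce the
nine output widths 256, 480, 512, 512, 512, 528, 832, 832, 1024; each block
holds 6 convolutions, for a census of 3 stand-alone + 54 inception-internal.
In the level numbering an inception block spans two levels, which is how 29
levels are counted.

The engine is a compact NumPy implementation (NHWC float32) with convolution
as a loop of GEMMs over kernel taps, exact for the layer set above and
bit-reproducible from a seed; gradients of every layer are verified against
central finite differences in the test suite. Training is SGD with momentum
0.9 (the conventional default for this model family), learning rate 0.01, 30
epochs, batch size 32, cross-entropy loss, and a stratified 20% hold-out
validation split evaluated every 50 iterations and at the end of training.
Optional inverse-frequency class weighting is off by default. A `width`
multiplier scales every channel count proportionally (minimum one channel per
branch) while preserving the topology; width 1 is the reference network.

Training data is drawn from peri-onset segments — 10 minutes before to 5
minutes after each seizure onset, clipped to the recording and merged when
overlapping — so negatives come from the pre-onset background of the same
recordings. Evaluation uses leave-one-subject-out folds: one model per
subject, each subject tested exactly once.

## Detection and evaluation

The trained model streams over a recording one sliding window at a time; each
decision uses only its own window's samples, so truncating the recording
reproduces the decision prefix exactly. Detection time is the start of the
first asserted-positive window — the earliest claim a causal system can make.
An optional smoothing parameter requires k consecutive positive windows
before asserting (default 1, no smoothing); an optional pre-onset tolerance
credits detections slightly before the annotated onset (default 0).

Each annotated interval is matched to the first asserted-positive window
whose start lies in `[onset − tolerance, offset)`: a true positive with delay
= window start − onset, or a missed event. At most one TP per interval;
further positives inside a matched interval are neither TPs nor FPs. Positive
windows outside every extended interval are grouped into consecutive runs,
one FP event per run. Event extraction is tested against an independent
exhaustive-scan oracle on hundreds of random configurations.

Window-level metrics score every decision against the overlap-rule label:
accuracy = 100·(TP+TN)/total, FP rate = 100·FP/(FP+TN) — the fraction of
truly seizure-free windows flagged positive, the only reading on a percent
scale — computed over all windows of the evaluated recording. Event
sensitivity is 100 · detected/annotated. Pooled reports sum event counts for
sensitivity and average per-case FP rate, accuracy and delay (delay over
detected events only). Percentages are reported to two decimals, half-up.
Per-window wall-clock latency can be instrumented; it is informational only,
never an acceptance gate, because it is hardware-dependent.

## Synthetic data

The generator targets the statistical structure the pipeline keys on, not
clinical realism. Background is 1/f noise (default exponent 1, RMS 20 µV — a
typical scalp-EEG background level) plus a 10-Hz alpha rhythm (10 µV) plus
white noise (5 µV), independent per channel and stationary. Seizures
superimpose a periodic train of exponentially decaying sharp transients
(default 4 Hz, 100 µV peak — a spike-and-wave caricature) plus band-limited
20–60 Hz noise calibrated per channel and per episode so total in-band power
during the seizure exceeds the local background by the configured boost
(default 20 dB); the calibration subtracts the spike train's own in-band
contribution, so the spectral contract holds on every channel even with the
random per-channel gains in [0.5, 1]. Amplitude-depression onsets (suppressed
background, no boost) can be generated behind a flag for negative testing;
they are not produced by default because the detector has no mechanism for
them.

What passing the synthetic benchmark shows: the full chain — filtering,
feature geometry, training, causal streaming, event scoring — recovers
strongly band-boosted seizures with low false-positive rates. What it does
not show: performance on real scalp EEG, with artifacts, electrode noise,
non-stationary background, inter-subject variability, or subtler ictal
signatures; the 20-dB boost is a deliberately strong, analytically checkable
effect.

## Desk-scale benchmark sizes

The leave-one-subject-out benchmark (`ictus.pipeline.loso_benchmark`) uses
three subjects, 300-s recordings with four 25-s seizures each (twelve
seizures total), architecture width 1/16, 8 training epochs, and a training
grid of one window every 2.7 s; test recordings are streamed at the full
89-sample hop. These sizes were chosen once so the whole benchmark runs on a
single CPU core in a few minutes; the detection conditions themselves — the
20-dB boost, three subjects, the reference window/STFT/filter geometry — are
fixed and not tuned.

## Known limitations

- The engine targets this architecture family; it has no GPU path, no
  dilation or grouped convolutions, and same-padding only for stride 1.
- EDF output quantizes to 16 bits over a per-channel symmetric range and pads
  recordings to whole 1-s records; sampling rates must be integers.
- The delay metric inherits the window grid: delays are multiples of the
  hop (≈0.35 s) relative to the first in-interval window.
- Amplitude-depression onsets are by design not detectable with a band-power
  feature; the generator's depression flag exists to demonstrate this, not to
  solve it.
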