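# Methods

This note documents the models and procedures `syrinx` implements, the
choices made where the design was genuinely open, and what the synthetic
corpora do and do not establish about real data.

## Problem setting

A song bout is annotated as an ordered list of labeled segments
`(onset_s, offset_s, label)`. Annotation is cast as frame classification:
every time bin of a spectrogram receives one of C classes — the bird's
syllable classes plus a reserved *background* class (index 0) covering
silent gaps, noises, and non-song calls. Background bins both absorb
non-song sound and delimit the recovered segments, which is what lets a
single model replace the separate segment-then-classify pipeline.

## Spectrograms and frame labels

Spectrograms are Hann-window STFT power matrices. With FFT length `nfft`
and hop `step` over a waveform of `n` samples at rate `fs`:
`T = floor((n − nfft)/step) + 1` time bins of duration `step/fs`, and
`nfft/2 + 1` frequency bins. Bin `i` covers the half-open interval
`[i·step/fs, (i+1)·step/fs)`; a bin belongs to an annotated segment when
its *center* falls inside the segment, so onset and offset rounding are
symmetric and the annotation → frame-labels → segments round trip is
exact to within one bin whenever gaps span at least two bins. Species
presets follow common practice: `nfft=512, step=64` with 176-bin windows
(Bengalese-finch-like), `nfft=1024, step=119` with 370-bin windows
(canary-like). Desk-scale experiments in the test suite use `nfft=256,
step=64` (129 frequency bins, 2 ms bins) and 88-bin windows to keep
single-CPU runtimes in minutes; nothing in the method depends on this
scaling.

Training spectrograms are standardized per frequency bin (mean/s.d. over
the whole training set); standard deviations are floored at 1e-6 because
synthetic corpora contain genuinely silent bins. Spectrogram thresholding
is available but off by default — flooring low-power values introduces
abrupt value changes that destabilize training and slightly worsen error.

## Network

`TweetyNet(cfg)` maps a window `(1, F, W)` to scores `(C, W)`:

| stage | output shape | notes |
|---|---|---|
| conv 5×5, stride 1, same pad, 32 filters, ReLU | (32, F, W) | |
| max pool (8, 1), stride (8, 1) | (32, ⌊F/8⌋, W) | frequency only |
| conv 5×5, 64 filters, ReLU | (64, ⌊F/8⌋, W) | |
| max pool (8, 1), stride (8, 1) | (64, ⌊F/64⌋, W) | |
| flatten per time bin | (W, 64·⌊F/64⌋) | |
| bidirectional LSTM, hidden H | (W, 2H) | H = features when "auto" |
| linear | (W, C) | |

No stage changes the time dimension before the linear layer; every input
bin gets a score vector. `F ≥ 64` is required (two 8× pools must leave at
least one frequency row); the configuration error spells out the
arithmetic. Full weight sharing is used (filters correlate with the whole
window); limited frequency-band weight sharing is deliberately not
implemented. A ReLU follows each convolution — the conventional block
design; the shape contract is unaffected by this choice.

The network runs on a small in-package reverse-mode autodiff engine over
numpy (`syrinx._tensor`): broadcasting add/multiply, matmul, sigmoid /
tanh / ReLU, basic indexing, reshape/transpose, stack/concat, stride-1
'same' convolution via im2col (adjoint computed as correlation with
flipped, channel-swapped filters), frequency max pooling, and a fused
softmax cross-entropy. Parameters and activations are float32; the test
suite gradient-checks the full network in float64 against central finite
differences. Initialization is the standard fan-in uniform scheme,
`U(±1/√fan_in)`, from a seeded generator.

## Training

Loss is per-bin cross-entropy; background bins contribute exactly like
syllable bins. Batches of (window, frame-label-vector) pairs are drawn by
a sampler that enumerates *every* possible window start in every training
spectrogram and visits each exactly once per epoch in an order that is a
deterministic function of (seed, epoch) — random windowing doubles as
translation-invariance augmentation. Optimization is Adam with lr 0.001,
betas (0.9, 0.999), eps 1e-8, weight decay 0, batch size 8. Every
`val_step` (default 250) steps the full validation set is scored;
training stops after `patience` (default 4) consecutive validations
without improvement, and the best-validation parameters are kept. Early
stopping monitors frame error only; the validation SER is recorded
optionally but does not gate stopping (computing it during training costs
more than it informs). Training is bit-reproducible given the seed and
thread count.

Whole bouts are predicted by tiling consecutive non-overlapping windows.
When T is not divisible by W the final window is right-aligned over the
last W bins and its scores win on the overlap — this avoids zero-padding
artifacts at the bout edge; the choice only affects ≤ W−1 bins per bout.

## Post-processing

From the score matrix: argmax per bin (ties to the lowest class index,
i.e. background when involved); maximal runs of non-background bins
become candidate segments; runs shorter than `min_segment_dur_s` are
discarded (their bins revert to background, single-pass semantics); each
surviving run is assigned its modal *non-background* label, overriding
every bin in the run. Majority-vote ties go to the earliest-occurring
label in the segment — deterministic and order-stable. Background bins
inside a run (impossible by construction of run recovery, but possible if
callers vote over arbitrary label vectors) are never counted as votes.
When the user sets no minimum duration, a data-driven default of half the
corpus's 10th-percentile syllable duration is available. The "raw"
(un-post-processed) reading of the output treats each maximal run of one
constant non-background label as a segment; label flips inside a syllable
therefore surface as insertions, which is exactly what the majority vote
repairs.

For inspection, scores are converted to per-bin likelihoods by
subtracting each column's minimum and normalizing the column to sum to 1;
this preserves the argmax, and an all-equal column maps to the uniform
distribution.

## Metrics

Frame error is the fraction of bins whose predicted class differs from
ground truth. The syllable error rate is the Levenshtein distance
(unit costs, no transpositions) between predicted and reference label
sequences, divided by the reference length; corpus-level SER is primarily
the mean of per-bout rates (the pooled ratio — total edits over total
reference length — is also computed, since the field convention is not
settled). Boundary attribution counts, among all frame errors, those
within two bins of a true onset/offset where exactly one of
(prediction, truth) is background; with a perfect prediction the fraction
is defined as 0 and flagged. The rare-sequence analysis finds, for every
context bigram a-b, followers at least four times rarer than the modal
follower, correlates their relative frequency with the frame error inside
those syllables (Pearson), and compares the rarer and more common halves
(split at relative frequency 1/8) with a two-proportion z-test.

## Amplitude segmentation

The classic segmenter thresholds an amplitude envelope, removes silent
intervals shorter than a minimum (merging their neighbors), then removes
segments shorter than a minimum duration — in that order. The envelope is
the rectified waveform smoothed by a centered moving average (default
2 ms); the smoothing window and rectification are configuration knobs
because labs differ in this convention. Onset is the first sample above
threshold; offset is the last sample above threshold plus one sample
period. Parameters are estimated from annotated song as: threshold =
median envelope value at all annotated onsets/offsets; minimum syllable
duration = 10th percentile of durations; minimum silent interval = 0.1th
percentile of gaps (percentiles by linear interpolation between order
statistics, which matters in the extreme tail). Note this recipe is
self-limiting: the duration filter sits at the 10th percentile of the
durations it was estimated from, so roughly a tenth of true syllables
fall below it by construction; the package's tests assert recovery
against that ceiling rather than pretending it does not exist.

## Learning curves

For each target duration, songs are drawn at random from a fixed pool
until the target is reached; the final song is clipped at the target, and
the draw is retried (bounded, with the missing classes reported) until
every syllable class is present. Each (duration, replicate) cell trains a
fresh network with a seed derived from the cell, so replicates differ in
both subset and initialization. All cells are evaluated on one fixed test
set, disjoint from the pool (checked by name) and hash-checked for
bit-identity across the curve; rows are persisted incrementally so an
interrupted curve resumes. Each cell reports frame error and SER, raw and
post-processed.

## Syntax statistics

Transition matrices count label bigrams within bouts (never across bouts)
plus one explicit end-of-song event per bout, row-normalize, then zero
entries below a 0.002 floor *without* renormalizing — the floored matrix
is a display/analysis convention, not a distribution.

Branch-point stability across two days is tested by permuting the day
labels of the pooled outcome list. The statistic is the maximum absolute
difference across outcome classes between the two days' outgoing
probability vectors (a per-outcome statistic is implicit in the maximum).
The permutation distribution is sampled exactly via multivariate
hypergeometric draws of day-1 outcome counts — equivalent to label
permutation but vectorizable — and the p-value uses the
`(1 + #{perm ≥ obs}) / (n_perm + 1)` convention, so it is never zero and
never below `1/(n_perm+1)`. A Bonferroni helper corrects across
(branch point, day pair) tests.

Probabilistic suffix trees model variable-order dependencies: each node
is a history suffix (most recent symbol last) storing its frequency among
all transitions and a next-symbol distribution including end-of-song.
Sequences are framed by a reserved start symbol (`^`) and the end symbol,
so start-anchored contexts are representable. Growth proceeds from the
root by prepending one symbol at a time; a candidate is added iff its
frequency ≥ `p_min` *and* the frequency-weighted KL divergence of its
next-distribution from its parent's exceeds `gain_threshold`. The gain
criterion's default is 0 (frequency-only growth) because the literature's
"adds information" rule is not given as a formula; analyses that need a
parsimony guard (e.g. depth-0 recovery on memoryless data) set a small
positive gain, and the tests use 0.01. Held-out sequences are scored by
the deepest matching suffix node, with additive smoothing
`ε = 1/(training transitions)` so novel events stay finite;
`p_min` is selected by minimizing the mean held-out negative
log-likelihood over ten random 90/10 splits. Canary analyses operate on
phrase sequences (repeat runs collapsed to one symbol); finch analyses on
raw syllable sequences.

## Synthetic corpora

The generator emulates the statistical structure the method assumes:
syllables are harmonic stacks (per-class fundamental, 1/k harmonic
roll-off, flat/ramp/bell amplitude envelopes, 2 ms edge tapers), song
follows a variable-order Markov syntax sampled to termination (capped at
500 syllables), gaps and durations are Gaussian with millisecond
quantization (so annotations survive the ms-precision CSV dialect
exactly), a Gaussian noise floor (default −60 dBFS) and 2–10 ms broadband
clicks (default 0.5 events/s, placed only in silence so ground truth
stays exact) provide non-song sound, and per-class gains spanning ≳20 dB
reproduce the regime where no single amplitude threshold segments every
syllable — demonstrated by a threshold-sweep test. Default sample rate is
32 kHz (recording rates are lab-specific; any rate ≥ 8 kHz works), gap
mean 30 ms with a 12 ms floor so gaps always span ≥ 2 analysis bins.
All randomness flows through explicitly passed seeded generators;
corpora are byte-reproducible.

What passing tests on these corpora shows: the machinery — label
conversions, training dynamics, post-processing, metrics, syntax
estimators — behaves as specified on data with the assumed structure.
What it does not show: performance on real song, which has vocal-tract
acoustics, amplitude and spectral drift, overlapping noise, and
annotator-dependent boundary conventions that the generator deliberately
does not model. Reported error rates on synthetic corpora are therefore
engineering checks, not biological claims.

## Numerical and operational choices

- Tie-breaks: argmax ties → lowest class index; majority-vote ties →
  earliest label in the segment; permutation p-values use the +1
  convention.
- Degenerate inputs: empty envelopes, empty references for SER,
  zero-variance frequency bins, all-equal likelihood columns, corpora
  without gaps, and too-short spectrograms all raise or fall back as
  documented in their docstrings.
- Desk-scale problem sizes used by the test suite: ~60 s training
  corpora, 129 frequency bins, 88-bin windows, ≤ 200 optimization steps,
  learning curves of 3 durations × 2 replicates at ≤ 30 steps per cell —
  chosen so the full pipeline exercises every code path in minutes on a
  single CPU.
- Checkpoints are single `.npz` archives embedding parameters,
  architecture, label map, normalizer, and training history, so
  prediction needs no side files.

## Known limitations

- No structured decoding (HMM/CRF smoothing) on top of the frame
  classifier, and no sequence-level loss; post-processing is the only
  sequence prior.
- The CPU implementation is for desk-scale experiments; training
  multi-hour corpora needs a GPU framework.
- PST node addition uses the KL-gain heuristic above; no significance
  test for node addition is implemented.
- The amplitude segmenter implements one envelope dialect
  (rectify + moving average); spectral-flux and other segmentation
  algorithms are out of scope.
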