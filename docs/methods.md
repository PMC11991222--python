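# Methods

This note records the modelling choices behind `habitmine`, the defaults
and why they were chosen, and what the synthetic test bed does and does
not demonstrate.

## Event model and labelling

A log line carries `(timestamp, sensor_id, value)` plus an optional
`Activity begin|end` annotation. Labelling assigns every event between a
`begin` and its matching `end` (inclusive) to that activity; everything
else gets the reserved class `Other`. Real logs are messy, so the reader
is deliberately forgiving: both the spaced and the fused (`Act=begin`)
annotation dialects are accepted, out-of-order files are stable-sorted by
timestamp with a warning, malformed lines are counted and skipped, an
`end` without a `begin` is ignored, and an interval left open at
end-of-file is auto-closed at the last event. When intervals overlap
(multi-resident recordings), the innermost — most recently begun —
interval wins; this is deterministic and matches the nesting intuition,
though any tie-break here is a convention rather than a fact about the
data.

## Tokenization and windows

Tokens concatenate sensor id and value with the timestamp dropped
(`"M011ON"`). Numeric (temperature) values are first discretised into
fixed-width bins, default 5 °C, because the token scheme presumes
categorical values; the bin width only needs to be coarse enough that a
thermostat's normal drift stays in one or two tokens. Indices are
assigned by descending training-split frequency (ties lexicographic),
index 0 is padding and index V+1 the out-of-vocabulary token; building
the vocabulary on the training split only avoids a subtle leak.

Windows hold the W most recent event indices and advance `step = 1`
events, so recognition can fire on every incoming event; left padding
keeps the most recent events at fixed positions, which is the stable
alignment for convolution. A window is labelled by its **last** event's
activity — the activity happening *now*, which is what a monitoring
system needs; a majority-label option exists for comparison. Windows are
cut across activity boundaries on purpose: the deployed setting is a
continuous stream, and re-segmenting per activity would leak boundary
knowledge the classifier is supposed to infer.

## Classifiers

All three models run on a small numpy layer library with manual
backpropagation (embedding, im2col 1-D convolution, max-pool,
nearest-neighbour upsample, masked LSTM, Adam, masked cross-entropy),
gradient-checked against central differences in the test suite. Floats
are float32; every initialisation and shuffle draws from an explicit
seeded generator, so training is bit-reproducible on one CPU.

* **U-Net** (primary): encoder of five double-convolution blocks
  (kernel 3, filters 64–1024) with max-pool 2 between blocks; decoder of
  four blocks (512–64) with upsample 2 and channel-concatenated skip
  connections; 1×1 projection to per-position class logits. Window
  lengths not divisible by 2⁴ are left-padded internally (SEW 25 runs at
  an internal length of 32) and the padding is masked out of both the
  loss and the prediction. Upsampling is nearest-neighbour resize
  followed by convolution; transposed convolution would serve equally.
  The network is trained as a sequence labeller — every non-padding
  position inherits the window label, per-position cross-entropy with
  padding masked — and a window prediction averages the per-position
  probabilities over non-padding positions before the argmax (ties break
  to the lowest class index). This is the simplest reduction consistent
  with training a segmenter but scoring a window classifier.
* **FCN** baseline: convolutions of 128/k8, 256/k5, 128/k3 (stride 1,
  length-preserving zero padding), global average pooling, softmax.
* **LSTM** baseline: 64-dimensional embedding into a 64-unit LSTM whose
  recurrence skips padded steps, then softmax on the final state.

Each model has a raw-index (one-hot) variant for the embedding ablation.
A `depth_scale` knob multiplies every filter count so desk-scale
experiments train in seconds — at 0.125 the U-Net has ~63× fewer
parameters — while the printed sizes remain the defaults for full runs.

Optimisation defaults (Adam, lr 1e-3, batch 64) are ordinary choices for
networks of this size; batch size mainly trades speed for gradient noise
here. Early stopping monitors validation negative log-likelihood and
restores the best epoch's weights after `patience = 5` epochs without
improvement, capped at 25 epochs in the pipeline defaults.

## Protocol and metrics

The outer split is stratified 70/30; stratified 3-fold cross-validation
runs inside the 70%, and test metrics are averaged over the fold models
(the pipeline's single-model path trains on fold 0). Windows are shuffled
before splitting; note that shuffling sliding windows places near-
duplicate windows on both sides of the split, so scores on this protocol
are optimistic relative to a temporal split — acceptable for comparing
architectures, not for absolute claims. Metrics are weighted F1
(support-weighted per-class F1) and balanced accuracy (mean per-class
recall over classes present in the test set), both reported ×100 and
cross-checked in the tests against an independent confusion-matrix
computation.

## Transactions, mining and the temporal filter

Behavior instances are maximal runs of identically-labelled consecutive
windows; runs shorter than 3 windows are discarded as classifier flicker,
and same-label runs separated by a discarded run are *not* merged.
`Other` segments are excluded from mining by default — they are gap
filler between annotated activities, not ADLs. The default transaction
scheme is one per calendar day with items `(activity, hour-of-day)`:
daily habits ("waking at 8", "walking at 10") are exactly day-level
co-occurrences at hour granularity. A sliding k-behavior n-gram scheme is
available for sub-daily structure.

FP-Growth is implemented from scratch (frequency-ordered FP-tree,
recursive conditional pattern bases); the test suite proves it
set-identical — itemsets, counts, rules, confidences — to a brute-force
lattice enumeration on hundreds of random databases. Rule generation
emits every confident split X → Z∖X of every frequent Z; output is
canonically ordered (support descending, then lexicographic) so runs are
diffable.

The temporal filter computes, per supporting transaction, the gap from
the latest antecedent behavior's end to the earliest consequent
behavior's start, and keeps a rule iff the **median absolute** gap is
within `max_gap` (default 30 min, on the scale of "one follows the
other"). The absolute value is a deliberate choice: a signed comparison
would let rules whose consequent precedes the antecedent by hours pass
any threshold, while an infinite threshold must leave the rule set
untouched. The median is robust to occasional schedule disruptions. A
consequence is that both orientations of a genuinely adjacent pair
survive; the directional claim comes from the rule statement itself, and
scoring matches antecedent/consequent exactly (a relaxed subset matcher
exists but is off by default). Precision follows TP / (TP + FP) and is
reported as undefined, not zero, for an empty habit set.

## The synthetic home

The generator emulates a single-resident apartment: activities occur at
normally-jittered clock times with log-normal durations (positive,
right-skewed), fire ON/OFF pairs from their own sensor sets at
per-activity rates, and are wrapped in begin/end annotations. Planted
habits trigger their consequent a truncated-normal gap after the
antecedent ends with adherence 0.95; decoy pairs co-occur on ≥80% of days
but hours apart. A temperature sensor logs every 30 minutes and 2% of
events are spurious. The default scenario (5 ADLs, 8 sensors, 60 days, 3
habits, 2 decoys) is sized so the whole pipeline — including U-Net
training — runs in minutes on one CPU; the schedule places each habit's
antecedent and consequent safely inside single hour bins so that hour-
level items are stable under jitter.

What passing on this generator shows: the pipeline recovers exactly the
planted temporal structure and rejects frequent-but-distant pairs, and
the classifier separates activities whose sensor signatures differ.
What it does not show: robustness to the things real homes add —
overlapping multi-resident activity, sensor failure and drift,
annotation errors, non-stationary schedules, and activities that share
sensors. Scores on the synthetic scenario are therefore upper bounds in
kind, not estimates of CASAS-scale performance.

## Problem sizes and numerical choices

Desk-scale defaults: SEW 25, a stratified cap of 3000 windows before
splitting, `depth_scale = 0.125`, ≤25 epochs. The acceptance script uses
exactly these sizes. Frequency thresholds compare `count / n ≥
min_support` in floating point; mathematically equal rationals round to
identical doubles, so the comparison is exact at the grid values used.
Degenerate inputs fail loudly rather than silently: empty transaction
databases, antecedents with zero support, single-class classifiers,
windows smaller than the pooling stack, non-finite losses and
sub-fold-size classes all raise with a message naming the problem.
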