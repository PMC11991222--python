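# habitmine

Activity recognition and habit mining for single-resident smart homes
instrumented with ambient binary sensors (motion, door, temperature).
The target application is unobtrusive monitoring of elderly people living
alone: classify the resident's activities of daily living (ADLs) from the
raw sensor event stream, then mine the classified behavior sequence for
*time-sensitive* association rules — habits such as "toileting a few
minutes after waking" — while discarding frequently co-occurring but
temporally distant behavior pairs that are not habits.

## Method

**Activity recognition.** A CASAS-dialect event log is a chronological
sequence of events `e_i = (s_i, t_i, v_i)` (sensor id, timestamp, value).
Events are tokenized NLP-style by concatenating sensor id and value
(`"M011ON"`), indexed by descending token frequency, and cut into
sensor-event windows (SEW) of fixed length W ∈ {25, 50, 75, 100} that
advance one event at a time, zero-padded on the left while the history is
short. A learned 64-dimensional embedding feeds a **1-D U-Net**: an
encoder of paired kernel-3 convolutions with filter counts
64–128–256–512–1024 and max-pooling 2 (a length-64 input traces feature
lengths 64→32→16→8→4), and a decoder (512–256–128–64) of nearest-neighbour
upsampling with channel-concatenated skip connections, ending in a
per-position softmax. The window's label is the argmax of the mean
per-position probability over non-padding positions. FCN (128/k8, 256/k5,
128/k3 + global pooling) and LSTM (64 units) baselines, each with and
without the embedding, are included for ablation. Training uses a
stratified 70/30 split with stratified 3-fold cross-validation inside the
training portion, Adam, and early stopping on validation loss; scores are
weighted F1 and balanced accuracy (mean per-class recall), both ×100.

**Habit mining.** Classified windows collapse into behavior instances;
each calendar day becomes a transaction whose items are
`(activity, hour-of-day)` pairs. A from-scratch **FP-Growth** mines all
itemsets with

    support(X→Y) = |T(X∪Y)| / |D|   ≥ min_support
    confidence(X→Y) = |T(X∪Y)| / |T(X)| ≥ min_confidence

via an FP-tree (frequency-ordered prefix tree, recursive conditional
pattern bases, no candidate generation). A **temporal filter** then drops
every rule whose median absolute gap between the latest antecedent
behavior and the earliest consequent behavior exceeds `max_gap` (default
30 min); the surviving rules are the habit set. Against a known ground
truth the habit set is scored by precision = TP / (TP + FP).

**Synthetic home.** Because the reference CASAS testbeds (ARUBA, MILAN)
require an external download, the package ships a simulator: five ADLs
over eight sensors on a jittered daily schedule, three planted short-gap
habits, two long-gap decoy pairs, periodic temperature readings and 2%
spurious noise, emitted as a standard annotated CASAS log. Every claim in
the test suite is checked against this generator's planted ground truth.

## Worked example

```python
from habitmine import default_scenario, generate, label_events, MiningConfig
from habitmine.pipeline import mine_stream

records, truth = generate(default_scenario())          # 60 simulated days
labelled = label_events(records)
cfg = MiningConfig(min_support=0.8, min_confidence=0.8, max_gap_s=1800)
result = mine_stream([lab for _, lab in labelled],
                     [e.timestamp for e, _ in labelled], cfg, truth)
print("rules before filter:", len(result.all_rules))
print("habits after filter:", len(result.habits.kept))
print("precision before/after: %.3f -> %.3f"
      % (result.eval_before.precision, result.eval_after.precision))
for h in result.habits.kept[:3]:
    print(sorted(h.rule.antecedent), "->", sorted(h.rule.consequent),
          "supp %.2f conf %.2f median gap %.1f min"
          % (h.rule.support, h.rule.confidence, h.median_abs_gap_s / 60))
```

prints

```
rules before filter: 230
habits after filter: 23
precision before/after: 0.013 -> 0.130
[('Sleeping', 0)] -> [('Toileting', 7)] supp 0.93 conf 0.93 median gap 5.6 min
[('Sleeping', 0)] -> [('MealPrep', 11), ('Toileting', 7)] supp 0.92 conf 0.92 median gap 5.6 min
[('MealPrep', 11)] -> [('Eating', 11)] supp 0.88 conf 0.90 median gap 4.8 min
```

The filter discards 207 of 230 confident rules — all of them decoys or
other long-gap combinations — while every planted habit survives, so
precision rises tenfold. The top surviving rule reads: on days the
resident goes to bed around midnight, toileting follows the end of sleep
within about six minutes.

The same pipeline is available from the shell:

```sh
habitmine run -o myrun          # simulate + train + classify + mine
habitmine run --use-true-labels -o myrun   # bypass the classifier
habitmine mine myrun/events.log --grid -o myrun   # support x confidence sweep
```

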