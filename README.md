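# nirsclench

Rest vs. tooth-clenching discrimination from prefrontal fNIRS hemoglobin
data, via grayscale image encoding and a small convolutional network.

Functional near-infrared spectroscopy (fNIRS) measures concentration
changes of oxygenated (oxy-Hb) and deoxygenated (deoxy-Hb) hemoglobin over
the cortex — here 22 channels over the prefrontal cortex at 10 Hz during a
block task: 300 s rest, 60 s tooth clenching at 40% maximum voluntary
contraction, 60 s rest. Neurovascular coupling makes oxy-Hb rise and
deoxy-Hb fall in task-active channels. `nirsclench` is for researchers who
want a fully reproducible, dependency-light reference implementation of
the image-based classification approach to such data:

1. **preprocess** — zero-phase 0.2 Hz low-pass; windows baseline (10 s) /
   rest (60 s, 600 samples) / clench (55 s after a 5 s exclusion, 550
   samples); per-channel baseline referencing; artifact masking of samples
   with |Δ − mean| > 2·SD per window, channel and species;
2. **imaging** — each 10 Hz sample becomes a 5×10-pixel grayscale frame
   (256 gradations, 0 = scope min, 255 = scope max; each channel a 1×2
   block). Three modalities: `oxy`, `deoxy`, and mixed `od` (oxy-Hb left
   pixel, deoxy-Hb right pixel). Frames touching a masked value are
   excluded; frames are squash-resized for the network;
3. **dataset** — random downsampling of the majority class until
   rest = clench, then a seeded partition of the 15 subjects into 5 groups
   of 3 for subject-grouped five-fold cross-validation (no subject ever on
   both sides of a split);
4. **classifier** — a five-conv / three-pool / three-FC CNN with two-way
   softmax output (numpy engine, deterministic under a seed; a `tiny`
   64-px preset trains in minutes on one CPU);
5. **evaluation** — per-fold confusion counts and the five
   identification-rate metrics

       Accuracy = (TN+TP)/(TN+TP+FN+FP)   Recall = TP/(TP+FN)
       Specificity = TN/(FP+TN)           Precision = TP/(FP+TP)
       F = 2·Recall·Precision/(Recall+Precision)

   with macro mean ± SD over folds, pooled ROC/AUC with DeLong 95% CI,
   and a stepwise Ryan-style comparison of the three networks' pooled
   accuracies;
6. **synthetic cohorts** — a seeded generator producing 15-subject
   cohorts with per-channel task effects convolved with a double-gamma
   hemodynamic response, physiological oscillations (cardiac, respiratory,
   Mayer wave), white noise and spike artifacts, so the whole pipeline is
   testable without any recording.

See `docs/methods.md` for the model, all defaults and their rationale.

## Worked example

`examples/03_grouped_cv.py` runs the full pipeline on a synthetic
15-subject cohort (frames every 2 s, tiny preset, 10 epochs):

```
=== oxy network ===
  group  accuracy  recall  specificity  precision  f_value
Group A     100.0   100.0        100.0      100.0      1.0
...
Average     100.0   100.0        100.0      100.0      1.0
     SD       0.0     0.0          0.0        0.0      0.0
pooled AUC 1.000 (95% CI 1.000-1.000), n = 241+241 test frames
```

Each row is one held-out subject group; Average ± SD is the macro
aggregate over the five folds. The synthetic effect profile is cleanly
separable at the default noise level, so accuracy saturates — the
interesting checks are the null cohort (chance-level accuracy, see
`tests/test_acceptance.py`) and the bookkeeping (600 rest + 550 clench
candidate frames per subject; OD valid frames are exactly the
intersection of valid oxy and deoxy frames).

The other examples: `01` simulate a cohort and verify effect recovery,
`02` encode and export frames as PNG, `04` the conventional per-channel
paired-t analysis with uncapped Bonferroni adjustment, `05` the metric
arithmetic and the multiple-proportion comparison.

A thin CLI wraps the same library:

```sh
nirsclench run-all --seed 1 --modality od --out runs/demo
nirsclench simulate --seed 1 --out runs/cohort   # per-subject CSVs
```

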