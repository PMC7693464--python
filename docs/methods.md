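# Methods

`nirsclench` re-implements, as a tested library, a pipeline for
discriminating rest from tooth clenching in prefrontal fNIRS hemoglobin
data: signal preprocessing, encoding of the 22-channel oxy/deoxy-Hb state
at each 10 Hz sample into a small grayscale image, subject-grouped
five-fold cross-validated CNN classification, and an evaluation stack
(identification-rate metrics, pooled ROC/AUC, multiple-proportion
comparison of the three image modalities). Because no public recording of
this protocol exists, the package ships a synthetic cohort generator whose
statistical structure matches what the analysis assumes; every stage is
validated against that generator.

## Signal model (synthetic cohorts)

One subject's recording is 420 s at 10 Hz (300 s rest, 60 s clench, 60 s
rest), 22 channels, two species (oxy-Hb, deoxy-Hb), units m(mol/L)·mm:

    x_ch(t) = beta_ch * (boxcar ⊗ h)(t) + noise_ch(t)

* `beta_ch` is the per-channel effect: a reference clench-minus-rest
  change profile (oxy up to +0.305 on the strongest channel, deoxy mostly
  small negative values) plus a subject-level Gaussian perturbation whose
  SD defaults to the reference across-subject SD divided by sqrt(15) —
  the across-subject SD of a 15-subject cohort mean, a deliberately modest
  between-subject spread.
* `h` is a double-gamma hemodynamic response kernel (peak 6 s, undershoot
  16 s, 32 s support), normalised to **unit area** so that a sustained
  boxcar plateaus at `beta_ch`. Unit-area (rather than unit-peak)
  normalisation is what makes the realized clench-minus-rest mean equal
  the configured effect — the generator's central calibration invariant
  (recovered to ~1% over the 55 s analysis window; the residual is the
  HRF rise).
* `noise_ch(t)` sums white noise (SD 0.03), three sinusoidal physiological
  components with per-channel random phase — cardiac 0.01 @ 1.2 Hz,
  respiratory 0.01 @ 0.3 Hz, Mayer wave 0.015 @ 0.1 Hz — and sparse
  bipolar spike artifacts (Poisson 2/min per channel, 1–3 samples wide,
  amplitude 6–12× the white SD), standing in for motion/contact events.

All randomness flows from one seed through per-subject substreams
(`numpy.random.SeedSequence.spawn`), so identical configurations are
bit-identical across runs and subjects are reproducible individually.

**Session drift is modelled but disabled by default.** The pipeline
references every sample to a single 10 s pre-rest baseline. Rest-window
samples lie 0–70 s from that baseline, clench-window samples 65–130 s.
Any drift whose timescale is comparable to the session therefore gives
clench frames systematically larger baseline-referenced offsets than rest
frames — the class label becomes partially decodable from
time-since-baseline alone. Empirically, a drift amplitude of 0.01 with a
300 s timescale lets the CNN classify an effect-free cohort at 60–70%.
Since the generator's defining null invariant is that an effect-free
cohort classifies at chance, the default drift amplitude is 0; the knob
(`NoiseProfile.drift_amp`, `drift_timescale_s`) remains available for
sensitivity studies of exactly this confound, which is equally real in
recorded fNIRS block designs.

What the generator does **not** emulate: optical physics (raw
intensities, Beer–Lambert conversion, probe geometry), spatial covariance
between neighbouring channels, superficial/systemic contamination shared
across channels, non-Gaussian motion artifact morphology, and
non-stationary oscillation amplitudes. Passing tests therefore demonstrate
the pipeline's correctness and calibration under this model, not
field performance on recorded data.

## Preprocessing

1. **Low-pass filter**: zero-phase (forward–backward) Butterworth,
   order 4, cutoff 0.2 Hz at fs = 10 Hz. Zero-phase filtering keeps window
   boundaries aligned with task events; attenuation at 1.2 Hz is ~120 dB,
   at 0.05 Hz ~0.
2. **Windows** (half-open `[start, end)`, so counts are exact): baseline
   = 10 s immediately before the rest window (100 samples), rest = 60 s
   immediately before clench onset (600), exclusion = first 5 s of the
   clench (hemodynamics lag the motor act), clench = remaining 55 s (550).
3. **Baseline referencing**: per-channel, per-species baseline mean
   subtracted from every rest/clench sample.
4. **2-SD artifact mask**: independently per window, species and channel,
   samples with |delta − window mean| > 2 × window SD become missing.
   Mean and SD are computed **once** on the unmasked deltas (single pass,
   no re-iteration), which makes the rule idempotent by construction. A
   zero-variance channel masks nothing (strict inequality). The anchor
   (per-window statistics on baseline-referenced deltas) is a design
   choice; note that with a per-window mean anchor the rule is identical
   on raw values and on deltas, since both differ by a constant. On
   Gaussian deltas the rule masks 2Φ(−2) ≈ 4.6% of samples per channel;
   since a frame needs all 22 channels, roughly 0.954²² ≈ 36% of frames
   survive per species — frame exclusion is aggressive by construction,
   not a bug.

## Image encoding

Each retained 10 Hz sample becomes one 5×10-pixel grayscale frame. Every
channel owns a 1×2 block; `oxy`/`deoxy` frames fill the block with that
species' code, `od` frames put the oxy code in the left pixel and the
deoxy code in the right. Unassigned cells (6 of 50) are 0.

* **Normalisation scope** (what maps to 0/255): per subject and per
  species, min/max over all unmasked rest+clench deltas of that subject.
  This keeps rest and clench comparable within a subject and prevents one
  extreme subject from flattening the rest; `per_frame` and `global`
  scopes are available for sensitivity checks. OD frames use each
  species' own scope, identical to its single-species image.
* **Coding**: `code = round(255·(v−min)/(max−min))`, round-half-up,
  clipped; a degenerate scope (max = min) codes mid-gray 127.
* **Layout**: rows of 4/5/4/5/4 channels following the 3×5 optode grid,
  4-channel rows left-aligned at column 1 (one blank column each side);
  anatomical region labels SFG {2,3,7,12,16,21}, IFG {14,18,19}, MFG the
  rest. The layout is plain data (JSON round-trip) so it can be corrected
  without code changes.
* **Validity**: a frame needing a masked channel value is excluded; an OD
  frame is valid iff the oxy and deoxy frames at that sample are both
  valid (so OD counts never exceed either species' count).
* **Resize**: squash (aspect ratio ignored) to the network's input side;
  nearest-neighbour by default so channel blocks stay piecewise-constant,
  bilinear available.

## Dataset construction

Class counterbalancing downsamples the majority class at random, without
replacement, to the minority count — cohort-wide, before fold splitting,
once per modality. The default strategy apportions removals across
subjects by largest remainder so no subject is disproportionately pruned;
a plain cohort-wide draw is available. The fold plan randomly partitions
the 15 subjects into 5 groups of 3 (generalised: any count divisible by
the fold count); each fold trains on 4 groups and tests on the held-out
one, so image→subject→group→fold is a function and subject leakage is
impossible by construction.

## Classifier

The topology is the classic five-convolution / three-max-pool /
three-fully-connected stack with a two-way softmax output. The engine is
a compact, self-contained numpy implementation (im2col convolution with
explicit backward passes, overlapping max pooling, He-initialised
weights, float32 throughout). It is deliberately minimal: deterministic
under a seed, single-threaded, and fast enough that the whole grouped CV
runs on one CPU core.

* **Full preset**: 256×256×1 input, conv 96@11/4 → pool 3/2 → conv
  256@5 (pad 2) → pool → conv 384@3, 384@3, 256@3 (pad 1) → pool → fc
  4096, 4096, 2. Used for structural and forward-pass checks.
* **Tiny preset**: 64×64×1 input, the same layer census with 8–12 filters
  per stage and fc 32, 16, 2. This is the preset used by the tests and
  the shipped experiments.
* **Training**: cross-entropy, SGD with momentum 0.9, initial learning
  rate 0.01, step decay ×0.1 at each third of the epoch budget, batch 32
  (tiny) — classic defaults, all overridable. Inputs are pixel codes
  scaled to [−0.5, 0.5]; optional mean-image subtraction is off by
  default. No pretrained weights.
* **Problem sizes**: the shipped experiments encode every 20th sample
  (2 s cadence → 30 rest + 28 clench candidate frames per subject) and
  train 10 epochs. At these sizes a full three-modality grouped CV on a
  15-subject cohort takes well under a minute per modality; the frame
  cadence (`frame_stride`) is 1 (native 10 Hz) by default in the library.

## Evaluation

With rest negative and clench positive: accuracy = (TN+TP)/total, recall
= TP/(TP+FN), specificity = TN/(FP+TN), precision = TP/(FP+TP), F = 2RP/
(R+P). A zero denominator yields NaN (flagged), never a silent 0. Fold
aggregation reports the unweighted (macro) mean ± sample SD (ddof = 1);
the pooled (micro) accuracy Σcorrect/Σtotal is reported alongside, since
the two differ whenever fold test sizes differ.

The ROC pools predictions across the five folds into one curve per
modality (per-fold counts remain available). The AUC 95% CI and the
two-sided p against AUC = 0.5 use DeLong's structural-components
variance (midrank implementation); the AUC itself is checked in tests
against the brute-force Mann–Whitney pairwise count, ties at ½.

Network accuracies are compared with a stepwise Ryan-style procedure on
two-proportion z-tests (pooled variance, no continuity correction):
proportions are rank-ordered and a pair spanning m ranks is tested at the
adjusted level α′ = 2α/(k·m), widest span first; pairs nested inside a
non-significant span are declared non-significant without testing. The
convention is isolated behind one function so an alternative adjustment
can be swapped in.

## Conventional channel analysis

Per subject, the clench-minute mean minus the rest-minute mean per
channel (this stage uses the **full** 60 s clench window, n = 600, unlike
the image pipeline's 55 s window — the two windows are distinct config
entries). Across subjects, a two-sided paired t-test per channel; the
Bonferroni column is raw p × 22, deliberately uncapped, so adjusted
values above 1 appear exactly as conventionally printed. Zero-variance
channels get NaN p-values. Because the default between-subject spread is
the reference SD/√15, synthetic cohorts yield many more significant
channels than a comparable recorded cohort would; the spread is a config
field.

## Numerical and degenerate-input choices

* Half-open windows and `round()` index arithmetic make all sample counts
  exact for compliant recordings.
* Round-half-up for gray codes (midpoint → 128); clipping as safety net.
* Mask threshold uses strict inequality, so exactly-constant channels
  (SD 0) mask nothing.
* Sub-seeds for folds, balancing and networks derive from the global seed
  via `SeedSequence` and stay below 2³¹.
* Empty training sets, single-class ROC inputs, zero totals in proportion
  tests, <2 subjects for t-tests, and non-partitionable subject counts
  all raise typed errors rather than returning degenerate numbers.

## Known limitations

* The numpy CNN is CPU-bound and unsuitable for the full 256-px preset at
  scale; it exists to make the full pipeline exactly reproducible and
  dependency-light, not to be a training framework.
* The synthetic cohort is linearly separable at the default noise level —
  grouped CV accuracy saturates near 100%, comfortably above the 80%
  calibration bound but not a statement about recorded data.
* The exact stepwise convention behind the named multiple-proportion
  procedure varies across texts; the α′ = 2α/(k·m) variant used here is
  one of several.
* Anatomical channel labels are a static lookup; no registration is
  performed.
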