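# Methods

## Problem setting

Affective state is self-rated on two 1–9 scales (valence, arousal) after
each stimulus trial; ratings are thresholded at 5 into low/high classes or
the four quadrants LVLA/LVHA/HVLA/HVHA (a rating of exactly 5 counts as
high, matching the quadrant convention — the binary wording leaves 5
unassigned, so one rule is used everywhere).  Recordings come from four
prefrontal electrodes (FP1, FP2, F3, F4; 10–20 system), the sparse montage
a comfortable wearable can realize.  The scientific difficulty is
*inter-subject variability*: a classifier trained on one set of subjects
transfers poorly to a new one, and the method under study counters this by
adapting to each new subject from a small labeled sample while avoiding
catastrophic forgetting of the source subjects.

## Preprocessing

Stage order: polyphase anti-aliased resampling (downsampling only; the
identity rate is a no-op) → removal of the leading baseline segment →
zero-phase (forward–backward) 4th-order Butterworth bandpass, 4–45 Hz →
channel selection/reordering → non-overlapping 1-s windows (trailing
partial windows discarded) → per-channel min–max normalization to [0, 1]
within each window.  Two geometry profiles are built in: `deap_like`
(40 × 63 s trials, 3 s baseline, 128 Hz) and `eppvr_like` (14 × 70 s
trials, 10 s baseline, 100 Hz); both yield 60 windows per trial.

Choices where the procedure is under-specified:

* **Normalization scope** is per channel *within each 1-s window* — the
  strictest reading of "normalize after segmentation", and it removes
  inter-window amplitude leakage.  A constant channel maps to all zeros so
  the output stays in bounds deterministically.  Whether per-window,
  per-trial or per-session scaling is intended is genuinely open; the
  per-window choice is the one all counts and tests use.
* **Filtering** is applied forward and backward (zero phase), standard EEG
  practice that avoids phase distortion; only the design order (4) is
  prescribed.
* **Upsampling** is disabled by default because the protocols only ever
  reduce the rate.

## Network

See the README for the stage-by-stage architecture.  Sizing rules that
matter:

* All convolutions are *valid* (no padding) and all pooling uses floor
  division — this is the only convention that reproduces the reference
  temporal-stage output length 34 = ⌊65/8⌋+⌊97/8⌋+⌊113/8⌋ at f = 128.
* Kernel widths floor non-integer `mⁱ·f` (f = 100 gives 50/25/12).
* Temporal branches concatenate along the **time** axis, spatial branches
  along the **spatial** axis — the only axes on which valid-convolution
  branch outputs are conformable.
* Convolutional stages use leaky rectification (slope 0.01); fusion and
  classifier stages use plain rectification.
* The fusion stage's published shape function (`fusion_output_shape`) is
  the package's own closed form; for the 4×128 geometry it traces
  (15,4,17) → (15,2,4) → flatten 120 → 118→59 → 57→28 → 26→13, ending at
  (128, 13).  The first depthwise kernel spans spatial rows and is clamped
  to the rows available, so the global-spatial-only ablation (1 row)
  remains well-formed.
* Classifier hidden sizes are 64 and 16 (the layer count is prescribed,
  the widths are not); dropout follows each hidden rectification.
* Initialization is fan-in-scaled uniform, fully determined by the model
  seed.

Ablation variants: single temporal scale (largest kernel only), global
spatial kernel only, no fusion stage (spatial output flattened straight
into the classifier), and adaptation without distillation (λ = 0).

### Implementation note

The framework is a small NumPy layer library with explicit reverse-mode
gradients (`sparseeg.nn`): im2col + BLAS matmul convolutions, batch
normalization with running statistics, inverted dropout, Adam.  Activations
and parameters are float32 (configurable; the gradient-check tests run the
whole stack in float64 against central differences).  Batch normalization
uses batch statistics whenever `training=True` — including adaptation on
small incremental batches — and running statistics at prediction.

## Adaptation (learning without forgetting)

The teacher is the converged pre-trained network and never changes (tests
checksum it).  The student inherits the feature extractor and re-draws the
classifier head.  The distillation term is implemented exactly as the
probability-space form: both probability rows are raised to the power 1/T
and renormalized, then compared by cross-entropy.  For softmax outputs this
softening equals softmax of logits/T, which is how the analytic gradient is
computed; the λ = 0 case reduces bit-exactly to plain fine-tuning (tested).
Numerical guards: probabilities are clamped at 1e-12 inside logarithms.
The incremental set is `⌈fraction·N⌉` windows drawn uniformly without
replacement (no stratification — the protocol states only random
selection); 2% of 2400 gives 48 and 2% of 840 gives 17, which pins the
ceiling rule.  The adaptation batch size is `min(batch_size, N_inc)`.

Repeats of an experiment re-draw **both** the incremental split and the
head initialization (which of the two the 5-repeat protocol re-draws is
unstated; re-drawing both is the conservative reading), with per-repeat
seeds `base + repeat` and the subject id mixed into the split seed.

## Synthetic generator

The generator emulates the features the pipeline depends on, not EEG
physiology (no volume conduction, no ocular artifacts):

* Band-limited sinusoids at theta/alpha/beta/gamma centres 6/10/20/35 Hz
  (all inside the 4–45 Hz analysis band), base amplitudes 3/5/2.5/1.5,
  random phase per (trial, band, channel); plus 1/f background (unit
  variance, spectrum flattened below 1 Hz) and white noise (sd 1).  With
  these defaults ≥ 95% of spectral power lies in 1–45 Hz (tested), so the
  bandpass retains the class information.
* **Valence code**: the F4/F3 alpha amplitudes are modulated by ±d with
  `d = 0.15·(valence − 5)·effect_size·asymmetry_gain + asymmetry_offset`,
  clipped to ±0.9.  **Arousal code**: beta+gamma amplitudes scale with
  `1 + 0.1·(arousal − 5)·effect_size`.  The baseline segment carries only
  the subject's resting offset, never the class-conditional part.
* **Subject shift** (all deviations proportional to `shift_scale`, which at
  0 yields the canonical subject exactly): per-channel gains (sd 0.15),
  band-centre jitter (sd 0.5 Hz), asymmetry-slope gain (sd 0.3), and a
  *resting asymmetry offset*.  The offset models the classic individual
  variation in frontal alpha asymmetry that is unrelated to momentary
  emotion; it is what makes naive cross-subject transfer genuinely fail
  (the regime in which unadapted baselines sit near chance) while leaving
  the within-subject class structure fully learnable.  Offsets follow a
  sign-balanced design grid (±0.45, ±0.225 cycled by subject id, scaled by
  shift) plus seeded jitter (sd 0.1): with desk-scale populations of ~4
  subjects, a pure Gaussian draw frequently realizes a homogeneous
  population with no meaningful shift, which would silently remove the
  phenomenon under study.  Slope heterogeneity is kept mild on purpose: a
  near-zero slope makes a subject's data intrinsically unclassifiable,
  a failure no adaptation method can address and not the one studied here.
* Ratings are uniform over [1, 4.5] ∪ [5.5, 9] by default (a flag restores
  the full range) so generated labels avoid the ambiguous boundary.
* Determinism: subject specs derive from `(seed, subject_id)` and trial
  seeds from `(seed, subject_id, trial_id)` via `SeedSequence` spawn keys;
  every dataset is a pure function of its arguments.

What passing tests on this generator do **not** show: robustness to real
artifacts (ocular, muscular), non-stationarity within trials, volume
conduction, or realistic label noise.

## Evaluation

LOSO over M subjects: pre-train on M−1, adapt on the target's incremental
fraction, test on the remainder; repeated with per-repeat seeds.  Metrics:
accuracy and F-score `TP/(TP+(FP+FN)/2)`; the multiclass F-score is the
macro average of one-vs-rest binary scores (the binary formula does not
generalize by itself; macro is the conservative convention).  Confusion
matrices are rows = actual, columns = predicted.  Summaries report mean ±
standard deviation pooled over subjects and repeats, with per-subject and
per-repeat breakdowns (which axis the protocol's reported deviation uses is
unstated).  Significance: two-tailed paired t-test on per-subject
accuracies (the test family behind reported T statistics is never named);
identical vectors return (0, 1), a nonzero constant difference raises
(zero variance, undefined statistic).

## Desk-scale study conditions

Full-scale replication needs the gated recording campaigns, so the
stochastic test studies run on synthetic data at reduced sizes, all seeds
fixed:

* **Adaptation study** (`tests/test_acceptance.py`): 4 subjects × 20 trials
  × 31 s (1 s baseline) at 128 Hz → 600 windows/subject; shift 1.0, effect
  1.0, dataset seed 11; 6 pre-training epochs; adaptation sets of 48
  windows (the full-scale 2%-of-2400 incremental size, reached here as
  fraction 0.08 of 600) for 15 epochs; 10 replicates per held-out subject;
  evaluation on fixed 192-window target and 384-window source subsamples.
  Asserted: mean post-adaptation target accuracy exceeds the unadapted
  model's, and mean source accuracy under distillation is at least that of
  λ = 0 fine-tuning, over the 40 paired replicates.
* **Null calibration**: same protocol with `effect_size = 0` (4 subjects ×
  10 trials, 3 pre-training epochs, 2 repeats, 2% splits); LOSO accuracy
  must lie within 3 standard errors of 0.5, where the standard error uses
  the number of independent *trials* (windows within a trial share label
  and features, so windows are not independent units).
* **Trainability**: 200 well-separated windows reach ≥ 95% training
  accuracy in 100 epochs.

## Known limitations

* The NumPy training loop is single-process and far slower than a GPU
  framework; full-scale (32-subject, 100-epoch) LOSO is possible but slow.
* Batch-normalization running statistics only partially converge during the
  15-epoch adaptation (momentum 0.1), a small systematic miscalibration
  inherent to the procedure at that epoch count.
* Adaptation from ~50 labeled windows with a re-drawn head is
  intrinsically high-variance; individual replicates can regress even when
  the mean improves, mirroring the large per-subject spread the protocol's
  summaries report.
* The synthetic class code is a single spectral mechanism per dimension;
  real EEG affect correlates are broader-band and weaker.
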