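# Methods

## The processing model

A night is a sequence of frames at 1 fps, typically 17:00–07:00 (14 h,
50,400 frames). All downstream quantities live on a 7-second interval
grid: frame `f` belongs to interval `f // 7`, a trailing partial
interval is retained, and a 14-h night has exactly 7,200 intervals. The
interval is the atomic unit — no sub-interval labeling exists after
prediction.

Per interval and individual, four frames (offsets 0, 2, 4, 6 of the
7-frame window; even spacing maximizes temporal coverage) are cropped
to the detector's box, resized to the classifier input (default
300×300), and also tiled row-major into a 2×2 multiple-frame image
(configurable to 1×4). Missing frames and missing detections become
black images; an interval whose four images are all black bypasses
classification and is Out. Crops are made before tiling
(crop → resize → tile).

**Detection.** The detector is a contract: image in, scored boxes out.
Boxes below `min_confidence` (default 0.5 — application-dependent and
meant to be tuned) are dropped; per (frame, individual) the
highest-confidence box survives, ties broken by smaller x-min. A box
fully outside the image counts as no detection. Coordinates follow the
Pascal-VOC/LabelImg convention. Detection density (kept boxes / frames
examined) is the first quality gate; the pipeline samples 4 of 7 frames
per interval, so density is measured over the sampled frames.

**Fusion.** The single-frame aggregate is the unweighted mean of the
four per-frame probability vectors — order-invariant, and consistent
with the final fusion step, which averages that aggregate with the
multiple-frame vector. The label is the argmax with ties broken by the
fixed class order Standing < LHU < LHD < Out (Standing < Lying < Out in
the binary task). Binary-task classifiers are independent models, not a
collapse of total-task outputs. A *hard example* is an interval where
the two classifiers' argmaxes disagree or the fused confidence falls
below τ (default 0.75).

## Postprocessing

Classification flicker — wrong labels in very short runs — barely moves
accuracy but corrupts phase counts and median phase lengths. Three
rules, applied out-merge → smooth → dismiss and iterated to a fixed
point:

1. **Out-flicker merge** (`out_merge_max_s`, default 56 s = 8
   intervals): an Out run no longer than the threshold, flanked on both
   sides by the same behavior, is relabeled to that behavior. Runs at
   the sequence ends or between differing behaviors are kept.
2. **Rolling smooth** (odd window, default 5 intervals): each interval
   takes the modal label of its centered window, truncated at the
   boundaries; ties keep the original label.
3. **Short-phase dismissal** (`min_phase_s` per label): iteratively the
   shortest phase with duration ≤ its label's threshold (inclusive —
   "up to 5 min" includes 5 min) is absorbed into its longer neighbor
   (ties absorb into the preceding one; first/last phases into their
   only neighbor). A phase spanning the whole sequence is never
   dismissed.

Default thresholds: binary task 300 s for Standing and Lying (rhythm
analysis at 5-min granularity); total task 60 s per behavior for
adults, 30 s for nonadults (nonadults show shorter phases, so a smaller
threshold sacrifices less real behavior). The Out dismissal threshold
equals the Out-merge threshold (56 s): Out flicker that straddles a
phase transition is unreachable by the merge rule (its flanks differ)
and by modal smoothing (a tie keeps the original label), so without a
dismissal path it would survive as a phantom Out phase and bias phase
counts; conversely, clustered Out flicker can otherwise chain through
dismissible behavior gaps into Out stretches the merge rule can no
longer reach. Genuine Out bouts last minutes (P(≤ 56 s) ≈ 0.3% under
the synthetic profile), so the systematic cost is negligible. All
values are YAML-overridable configuration.

A single rule pass is not idempotent (smoothing can shrink an Out run
below the merge threshold), so `apply_ruleset` repeats the pass until
the sequence stabilizes — almost always 2–3 passes, with a hard cap of
100. This makes postprocessing idempotent by construction and keeps the
whole-pipeline comparison (prediction vs annotation, both
postprocessed) well defined.

Rules are applied to *both* the prediction and the manual annotation
before any comparison, separating the methodological error (classifier
chain vs postprocessed truth) from the systematic error (postprocessed
truth vs raw truth, reported by `systematic_error`).

## Evaluation

Accuracy is the fraction of matching intervals; the per-class f-score
is `tp / (tp + 0.5 (fp + fn))`. A class absent from both sequences has
an *undefined* f-score, reported as missing rather than 0 or 1.
Misclassified runs are maximal runs of a constant (truth, prediction)
pair, so each run has a well-defined confusion type. All phase-statistic
deviations are signed (prediction − truth) to expose the direction of
bias. Nights with ≥ 20% Out in either sequence are dismissed from
evaluation — they carry no usable evidence about the activity budget.
Continuous annotations (subject, behavior, start, stop) are rasterized
to the grid by the interval-midpoint rule; uncovered time is Out.

## Presentation

Activity budgets are unweighted means of per-night interval
percentages, optionally normalized over non-Out states. The population
timeline aligns nights by clock time of night start (17:00 and 18:00
starts coexist); at each timepoint the state fractions are computed
over the non-missing (night, individual) pairs — shorter nights are
excluded from denominators, not zero-filled — and smoothed by a
centered rolling mean. Three minutes at 7-s resolution gives 25.7
intervals; the window is the nearest odd integer, 25. The rolling mean
is linear, so per-timepoint fractions keep summing to one. Nights are
pooled equally across individuals.

## The synthetic-data generator

The generator emulates the nightly behavior of stabled ungulates (the
study system is the common eland) as an alternating semi-Markov
process:

* Standing and Lying bouts alternate; bout durations are log-normal
  with shape σ = 0.6 and demographic medians (minutes):

  | demographic | Standing | Lying | LHD |
  |---|---|---|---|
  | adult male | 30.8 | 89.6 | 4.6 |
  | adult female | 35.5 | 59.3 | 3.7 |
  | nonadult | 21.2 | 78.5 | 4.4 |

  The log-normal family is a modelling choice (only medians and
  quartile orderings are constrained by observation); it is
  configurable, and recovery checks target medians only.
* Inside each Lying bout, LHU stretches and LHD sub-bouts alternate,
  starting with LHU: LHD (head resting on the ground, the REM-posture
  proxy) is entered only from LHU, and one binary Lying phase can
  contain several LHD events. The LHU gap medians (55 / 50 / 15 min
  for adult female / adult male / nonadult) are calibrated so nightly
  LHD phase counts land near the observed per-group bands (adults
  roughly 7–11, nonadults far more).
* Out bouts (Poisson, default 0.1 /h; log-normal duration, median
  300 s) start on Standing intervals and are clamped to the Standing
  bout they start in: an animal must be on its feet to leave the
  camera's field of view, so ground-truth Lying bouts are never
  interrupted by Out. Detector dropout *during* lying is prediction
  noise, not ground truth, and lives in the noise model.
* Nights are truncated at exactly 14 h (7,200 intervals). The final
  bout is cut short, exactly as a real observation window cuts bouts;
  recovered medians therefore sit a few percent below the underlying
  bout medians, matching how the observed statistics are produced.

**Noise model.** Per-interval confusion flips (row-stochastic matrix),
flicker bursts (Poisson arrivals, geometric lengths with optional cap,
uniformly chosen wrong label), and detection dropout (per-frame miss
probability; an interval turns Out only when all four sampled frames
are missed). What the generator does *not* emulate: real image
statistics, truncation/occlusion structure, correlated detector
failures, circadian drift within the night, or social interaction
between individuals. Passing tests demonstrate the correctness of the
pipeline's bookkeeping and rules under the stated stochastic model —
not the performance of any particular detector or classifier on real
footage.

**Renderer.** Deliberately crude shape coding on a noisy background:
tall rectangle = Standing; flat rectangle with a raised head blob =
LHU; flat rectangle with a head blob at ground level = LHD; nothing =
Out. The exact foreground bounding box is emitted as VOC XML. The
shape-heuristic mock classifier inverts this coding from the resized
crop alone (foreground fill fraction and the vertical placement of
background), giving a deterministic, weights-free stand-in that makes
the end-to-end identity of the chain testable.

## Validation experiment designs and problem sizes

* *Metric oracles*: 1,000 random 4-class pairs of length 200; exact
  equality against an independent confusion tally (plus a scikit-learn
  cross-check in the unit tests).
* *Dismissal oracle*: exhaustive comparison over all ternary sequences
  of length ≤ 12 (797,160 sequences) against a from-scratch fixpoint
  reference; 2-interval thresholds make short-length interactions
  dense.
* *Flicker suppression*: 50 nights, bursts at 3 /h, geometric mean 3
  intervals capped at 7 (49 s — strictly below both the 56 s Out-merge
  and the 300 s dismissal thresholds), 1% iid flips, no dropout.
  Postprocessed prediction vs postprocessed truth: ≥ 99% interval
  agreement and per-class phase counts within ±1 per night.
* *Parameter recovery*: 200 adult-female nights, binary rules applied
  as for real statistics; pooled Lying-phase median within 10% of the
  59.3-min profile median and median nightly Lying phase count in 7–9.
* *End-to-end identity*: one noise-free rendered 7,200-interval night
  through file-backed detection, encoding, both mock classifiers,
  fusion and postprocessing; the generating sequence is reproduced
  exactly.
* *Night filtering*: 20 nights, 5 with long Out stretches (40-min
  bouts); the ≥ 20% rule dismisses the Out-heavy ones while
  short-flicker nights — whose dropout the postprocessor repairs —
  are retained.

These sizes run in a few minutes on one CPU; all randomness is derived
from a single base seed via `numpy.random.SeedSequence`.

## Known limitations

* Thresholded rule engines trade a systematic error (real short events
  dismissed) against the methodological error (flicker); the defaults
  here favor rhythm-level analyses and will erase genuine sub-minute
  events.
* Label-level smoothing (modal window over labels, not probability
  vectors) discards calibration information the classifiers may carry.
* Whether Out interrupts a behavioral phase for phase counting is a
  convention; here Out terminates a phase, which postprocessing makes
  largely moot since short Out runs are repaired before counting.
* The BORIS-style rasterization uses the interval midpoint; behaviors
  shorter than half an interval can vanish.
* The mock classifier is exactly invertible on renderer output and says
  nothing about real-image performance; it exists to validate the
  plumbing around the network slots.
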