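# Methods

## Presence, not counts

The detector emits zero or more class-labelled detections per 1-fps
frame. All downstream temporal criteria are phrased in *seconds of
behavior*, so the pipeline collapses detection multiplicity: a class is
present in second *t* iff at least one detection of that class with
confidence ≥ τ falls in that frame. The operating threshold τ = 0.45 is
the detector's deployment setting; the filter is inclusive (≥ τ), the
usual detector convention. Timestamps are 0-based integer seconds of
day; a day is exactly 86 400 samples.

## Bout model

A bout of class *c* is governed by two integers: the onset threshold
*o(c)* (5 s for aggression, 3 s for ear and tail biting — short
incidental contacts of 1–2 s are deliberately excluded as noise) and the
shared termination gap *g* = 5 s.

* **Onset.** Scanning the presence series, a bout opens at the first
  second of the first run of ≥ *o(c)* consecutive present seconds.
  Sub-threshold runs that precede onset are discarded even when they lie
  within *g* seconds of the qualifying run: the bout *starts when the
  behavior occurs for ≥ o(c) s*, and the earlier fragments never met
  that bar.
* **Bridging and termination.** Once open, any absence shorter than *g*
  is bridged — it neither closes the bout nor stops its duration clock —
  and any presence, even a single second, extends the bout. The bout
  closes when *g* consecutive absent seconds elapse; its end is one past
  the last present second.
* **Duration.** Intervals are half-open `[start, end)`; duration is
  `end − start`, the difference of the recorded timestamps. Bridged gap
  seconds therefore count toward duration. (The alternative — summing
  only present seconds — is defensible; the timestamp-difference
  convention was chosen because start/end timestamps are the recorded
  primitives, and it is applied identically to AI and manual streams so
  comparisons are unbiased.)
* **Day boundary.** Series are per-day; a bout open at midnight is
  truncated at 86 400. All reported outputs are per-day, so no bout
  spans days.
* **Class independence.** Classes are segmented separately and may
  overlap freely; no mutual-exclusivity constraint is imposed, since
  aggression can co-occur with ear or tail biting in one interaction.

Two implementations exist: an online second-by-second hysteresis scan
(`find_bouts`) and an offline run-merging construction
(`find_bouts_oracle`: merge maximal presence runs separated by < *g*
into blocks; one bout per block, anchored at its earliest qualifying
run). The test suite proves them equivalent exhaustively on every
binary vector of length ≤ 18 and on 1000 random day-length vectors,
plus boundary and property checks (monotonicity under added presence;
with *o* = *g* = 1 bouts reduce to maximal runs).

## Daily and weekly metrics

Per class per day: bout count, total duration (s), mean duration per
bout (undefined — reported missing, never zero — on bout-free days).
Weekly values are arithmetic means of the daily values; duration per
bout is averaged over days with ≥ 1 bout only (a mean of daily means,
not a pooled per-bout mean — it matches the per-day output structure).
Days lost to camera gaps are excluded from the weekly mean with a
warning; nothing is imputed.

Growth: ADG = (BW_end − BW_start)/days on pen-mean weights; ADFI
converts pen-total weekly intake to per-pig daily intake, with hay eaten
from the enrichment basket added to the treatment group's intake and no
dry-matter correction; FCR = ADFI/ADG, explicitly undefined (never a
silent infinity) when ADG ≤ 0. Welfare scores are ordinal — ear lesions
0–3 per ear (pig score = mean of both ears), tail lesions 0–4, fecal
consistency 0–3 — validated against their ranges and averaged to pen
level, the experimental unit.

## Detection evaluation

IoU is intersection over union of axis-aligned pixel boxes. For
P/R/F1, predictions are matched greedily in descending confidence
(ties broken by input order, a stable sort, for reproducibility) to
unmatched same-class, same-image ground truths at IoU ≥ 0.5. AP uses
*all-point* interpolation: the PR curve is swept over the full
confidence ranking (no confidence cut) and the monotone precision
envelope is integrated over recall. The 101-point COCO variant would
differ in the third decimal at small n; the all-point form is exact for
the hand-derivable fixtures used as oracles. mAP50 is the unweighted
mean over classes that have ground truth; a class with no ground truth
has undefined AP and is excluded with a warning. The confusion matrix
filters predictions at the deployment confidence 0.45, then assigns
prediction–truth pairs greedily by descending IoU *regardless of class*,
so genuine class confusions land off-diagonal; unmatched truths fall in
the background row and unmatched predictions in the background column.
The normalised variant divides each true-class column by its sum.

A note on published operating points: F1 recomputed as 2PR/(P+R) from
per-class precision/recall tables reproduces some printed F1 values to
3 d.p. but not all — rounded inputs cannot always reproduce statistics
computed on unrounded data. The package asserts only the reproducible
rows and treats the rest as a rounding artifact, not a defect.
The same applies to FCR recomputed from rounded group-mean ADG/ADFI.

## Agreement statistics

The paired unit is class × day. For each class, per-day event counts,
total durations and mean durations per bout from the two sources are
compared with Pearson *r* (scipy) and ICC(A,1) — McGraw & Wong's
single-measure, two-way random-effects, absolute-agreement intraclass
correlation, computed from the ANOVA mean squares with k = 2 raters:

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))

clipped to the reporting range [−1, 1], and cross-checked in the tests
against `pingouin.intraclass_corr`. Unlike *r*, ICC(A,1) penalises
systematic offsets: a stream that halves every duration keeps *r* = 1
but drops ICC below 1. Cohen's κ = (Po − Pe)/(1 − Pe) is computed on
per-second binary presence labels pooled over the class's days (the
degenerate Po = Pe = 1 case reports 1), cross-checked against
scikit-learn. κ is *not* computed on the continuous metrics — no
defensible discretisation exists for counts and durations — so the κ
column of the report carries the per-second value on every metric row of
its class. Bout-level alignment matches each AI bout to the manual bout
sharing the greatest temporal overlap, greedily, each bout used at most
once, positive overlap required. Statistics with fewer than 2 paired
units or degenerate variance are reported missing with a warning, never
silently NaN-propagated.

## Synthetic generator

The generator replaces the unavailable recordings and trained network
with the simplest stochastic model that exercises every pipeline branch:

* **Bout process.** Daily bout count per class ~ Poisson(base ×
  group-multiplier × exp(trend × (day − 1))). Defaults: base rates
  59.70 / 325.64 / 116.95 bouts·day⁻¹ (aggressive / ear / tail, the
  control week-1 regime), treatment count multipliers 0.52 / 0.42 /
  0.27 (week-1 control-to-treatment ratios), trend −0.03 day⁻¹
  (matching the observed ~2-fold decline over four weeks). Durations
  are rounded lognormals (μ = 3.14 / 3.17 / 3.02, σ = 0.6, giving mean
  durations near 28 / 28 / 25 s) clipped below at the class onset
  threshold. Bouts are placed by the spacings construction — sorted
  uniform offsets added to the cumulative duration-plus-gap — which
  guarantees same-class separation ≥ the termination gap without
  rejection loops, so a noise-free schedule is *exactly* recoverable by
  segmentation (a property test over 100 seeds). Expected occupancy
  beyond 86 400 s raises an error rather than producing a degenerate
  packing.
* **Detector noise.** Independent per-second Bernoulli misses (default
  0.05) and Poisson false-positive single seconds (default 5
  day⁻¹class⁻¹), confidences ~ 0.45 + 0.55·Beta(5, 2) so every rendered
  detection survives the default filter (sub-threshold behavior is
  tested with explicit low-confidence fixtures). Real detector errors
  are bursty and occlusion-correlated; the independence assumption is a
  declared simplification, so passing recovery tests bound algorithmic
  error, not real-world detector error.
* **Manual coding.** Whole-bout misses (default 0.05) and rounded
  Gaussian boundary jitter (default sd 2 s), end kept after start.
* **Box fixtures.** Random rectangles with uniform classes; predictions
  perturb them by corner jitter, drops, class flips and spurious boxes
  at configured rates.

Every output is a pure function of (seed, arguments), via seed-sequence
derivation with stage/group/day/class salts. Moment tests check the
Poisson rate (10⁴ days, 3 SE), miss rate, FP rate, half-normal jitter
displacement and class-flip fraction; a 1000-replicate check confirms
the simulated enrichment effect's sign is recovered in ≥ 99% of 28-day
studies at base rate 20 and multiplier 0.5.

What the generator does *not* emulate: individual pig identity, spatial
movement, diurnal activity structure (bouts are uniform over 24 h),
correlated detector failures, and inter-observer disagreement beyond a
single noisy observer. Agreement values obtained on synthetic data
characterise the pipeline under the configured noise, not the field
performance of any particular detector.

## Problem sizes and numerical choices

Stochastic suites run at fixed, seeded sizes chosen to make the checks
sharp at desk scale: exhaustive bout-equivalence to vector length 18,
10³ random day-length vectors, 10² noise-free recovery seeds, 10⁴
simulated days for rate recovery, 10³ treatment-effect replicates.
Statistical assertions use 3-standard-error bands. Undefined statistics
(FCR at ADG ≤ 0, precision at TP+FP = 0, AP without ground truth,
duration per bout without bouts, correlations of constant series) are
surfaced as missing values or errors, never coerced to 0 or ∞.
`scripts/acceptance.py` recomputes the headline quantities from scratch
at the same problem sizes (300 day-length vectors for the
oracle-agreement rate) with all randomness derived from `--seed`.
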