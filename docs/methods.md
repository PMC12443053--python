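# Methods

## Scratch-bout detection model

Detection is rule-based, mirroring the "multi-condition" event logic of
commercial video-tracking software: per-frame channels are smoothed, each
clause of a criterion is thresholded, a frame is a candidate when every
clause holds, and candidate runs become events.

Two criteria run in parallel:

| clause | criterion A | criterion B |
|---|---|---|
| body elongation (10-sample avg) | < 47 % | < 46.5 % |
| activity (10-sample avg) | ≥ 0.1 % | ≥ 0.26 % |
| distance moved, nose (lowess-9 track) | — | < 0.58 cm/frame |
| distance moved, center (lowess-9 track) | — | < 0.3 cm/frame |
| velocity, nose (10-sample avg) | — | < 12 cm/s |
| velocity, center (10-sample avg) | — | < 5 cm/s |
| nose point in feeder zone | — | excluded |
| minimum event duration | 1.0 s | 0.66 s |

Comparison directions are exactly as printed in the criteria: upper
bounds strict, the activity floor inclusive. An A-event is kept only if
its best overlap against any B-event is at least 20 %; the retained
interval is the A-event (A is the broad detector, B the validator), and
many A-events may share one B-event. The audit trail of counts surviving
each stage replaces the original workflow's manual verification step.

Deliberate interpretation choices where the software semantics are not
published:

* **Smoothing before thresholding.** The per-clause "Average: 10" is read
  as a 10-sample centered moving mean applied to the channel before the
  threshold; the even window puts its extra sample on the trailing side.
  Truncated windows at the recording edges (no padding — smoothing never
  invents data).
* **Lowess "9"** is a 9-sample local window, tricube weights, degree-1
  local fits, truncated at endpoints. At interior frames the symmetric
  window makes the slope term cancel, so the fit reduces to a fixed
  weighted average (implemented as one convolution); endpoints get the
  full weighted regression. Collinear tracks are exact fixed points.
* **Overlap denominator.** "Overlap of < 20 %" does not name a
  denominator; the shorter event's duration is used (symmetric,
  conservative) and is configurable.
* **Missing samples** (animal not detected) stay NaN through smoothing
  and make every predicate false: no bout can start on unseen frames.
* **Session-start gating** (center point detected ≥ 5 s and activity
  > 0.05 %) is available as `trim_preamble` and enabled in the CLI
  pipeline; the library default detects from frame 0, since generated
  sessions begin with the animal present.

Duration comparisons carry a 1 ns slack: durations are integer multiples
of the frame period and the slack only absorbs float representation
error, never admitting a genuinely shorter event.

## Synthetic sessions

The generator scripts channel levels directly (the tracking software's
"activity" and "elongation" formulas are proprietary; the detector
consumes channels, not pixels). Baseline is a quietly alert animal:
elongation 55 %, activity 0.05 %, stationary at the arena center — frames
that fail both criteria. Embedded bouts set the scratch signature
(elongation 40 %, activity 0.5 %, 0.01 cm/frame nose wiggle); three
distractor archetypes populate the complement so every clause is
exercised: locomotion (elongation 70 %, activity 5 %, 8 cm/s run), rest
(activity 0), and feeder visits (scratch-like channels with the nose
inside the feeder zone — these pass criterion A and are rejected only by
B's zone clause, stressing cross-validation). Default sessions are 12 h
at 25 Hz with 20 bouts of 1.2–6 s and 20 distractors placed in disjoint
slots; the frame rate is configurable (no canonical value exists for this
kind of recording).

Noise is additive Gaussian per channel, clipped to the channel range.
The `calibrated_noise()` preset (elongation SD 2 %, activity SD 0.015 %,
position SD 0.005 cm) keeps every smoothed-channel level at least ~2 SD
from its nearest threshold, so detection remains near-exact while the
channels are visibly noisy. What passing tests show is that the decision
logic is implemented exactly and is robust at those margins — not that
real scratching is this cleanly separated from thresholds. Real
recordings have graded postures, tracking dropouts, and bout-internal
structure the generator does not model; true bout duration and inter-bout
interval distributions are free parameters, not estimates.

## Removal experiments and survival analysis

Each tick draws a latent removal time by exact inverse-CDF sampling from
its group's piecewise-constant hazard (rate λ per hour, zero before an
optional onset). Removals are only noticed at scheduled checks, so the
recorded event time is the first observation time at or after the latent
time — the right endpoint of the censoring interval, matching how count
decrements are actually observed (a midpoint-style coding can be had by
shifting the schedule; full interval-censored estimation is out of
scope). Ticks attached at the end of observation are right-censored.

The Kaplan-Meier estimator, Greenwood variance, and 95 % bounds via the
log(−log S) transform are implemented directly (and cross-checked against
an independent library implementation and a redistribute-to-the-right
oracle in the tests). Censoring tied with events at the same time keeps
the censored tick in the risk set at that time. With no events the curve
is identically 1 and a warning, not an error, is raised.

The Peto & Peto modified Gehan-Wilcoxon statistic uses weights
`w_i = prod_{t_j <= t_i} (n_j - d_j + 1)/(n_j + 1)` — one of several
left-continuous variants in the literature; the exact form used is echoed
in the result's `weights_used` field for auditability. The statistic is
`U' V⁻¹ U` over the first k−1 group margins with the hypergeometric
(co)variance at each distinct event time (ties pooled into d_i), referred
to chi-square with k−1 degrees of freedom; a seeded group-label
permutation p-value is available as a small-sample alternative.
Pairwise comparisons are unadjusted by default (Holm adjustment is a
flag), since no adjustment procedure is canonical here.

Calibration at desk scale: with 30 ticks per group, hourly checks over
48 h, and equal hazards λ = 0.03/h, the asymptotic test's empirical
type-I error over 1000 replicates sits inside [0.03, 0.07]; at hazard
ratio 4 (0.015 vs 0.06/h) power exceeds 0.8 by a wide margin. These sizes
are the package's reference simulation conditions and are what
`scripts/acceptance.py` re-runs.

## Ancillary statistics

* **Scutal index** = alloscutum length / scutum width; engorgement grows
  the numerator while the sclerotized scutum stays fixed.
* **Δ perfusion** = mean(ROI) − mean(background) over a 20-s time of
  interest inside a 1-min recording (default TOI 20–40 s). Common offsets
  and common linear drift cancel exactly.
* **Hourly bout distributions**: counts in 1-h tumbling bins over bout
  start times, normalized to probabilities; surprisal −ln p in nats, NaN
  for empty bins; zero-bout sessions flagged rather than raised. The KS
  comparison is applied to raw hourly counts by default (probabilities or
  surprisals are equally admissible inputs; the choice is the caller's).
* **Kolmogorov-Smirnov**: D evaluated at pooled order statistics (ties
  well-defined); p either from the asymptotic Kolmogorov distribution at
  the effective sample size or by label permutation — enumerating all
  C(n+m, n) splits exactly when that count is ≤ 200 000, sampling
  otherwise.
* **Mann-Whitney U**: U counts x > y pairs with ½ for ties. The exact
  two-sided p uses the full null distribution of U computed by the
  standard counting recurrence (identical to enumerating all
  interleavings, tie-free samples only, n·m ≤ 10⁴ by default); otherwise
  the tie-corrected normal approximation with continuity correction.
* **Scratch-vs-ticks association**: Pearson and Spearman correlations
  plus a transparent permutation test — group labels shuffled against the
  standardized bivariate observations, statistic = mean pairwise squared
  centroid distance. This replaces an omnibus MANOVA-style fit with a
  distribution-free equivalent whose null calibration is itself tested.

All seeded procedures use `numpy.random.default_rng`; a master seed
spawns per-stage substreams, so one integer reproduces an entire pipeline
run byte-for-byte (the run manifest records the config hash and seed).

## Problem sizes

Default test and acceptance runs use: ten 12-h sessions at 25 Hz
(1.08 M frames each) per detector-recovery condition; 1000 replicates for
type-I error and 500 for power (30 ticks/group); 1000 randomized cases
for event-filter exactness; 200 randomized series (up to 10⁴ frames)
for reference-implementation equivalence. These sizes keep Monte-Carlo
error comfortably inside the asserted bands.

## Known limitations

* The generator's piecewise-constant channels make detection boundaries
  sharp; graded posture transitions would blur event edges more than the
  smoothing windows do here.
* Ticks are treated as independent; per-animal clustering of removal
  times (frailty) is not modeled, and neither are left truncation or
  competing risks such as natural detachment to repletion (both censoring
  and event codings of detachment are supported at the record level).
* The asymptotic chi-square reference for the Peto-Peto test is known to
  be conservative for very small, heavily tied datasets — the permutation
  option exists for exactly that case.
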