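# iitr — itch-induced tick removal analysis

Hosts that have been sensitized by previous tick exposures develop an itch
response at the bite site and scratch attached ticks off within the first
day or two of attachment. Quantifying that behavior takes two analysis
chains that this package implements as a tested, reusable library:

1. **Scratch-bout detection** from video-tracking channel exports
   (per-frame body elongation, activity, nose-/center-point positions,
   zone membership). A scratch bout is a contiguous epoch passing two
   multi-condition criteria — a broad one (smoothed elongation < 47 %,
   activity ≥ 0.1 %) and a strict one (elongation < 46.5 %, activity
   ≥ 0.26 %, near-zero distance moved and velocity on the smoothed track,
   nose outside the feeder zone) — followed by duration floors (1 s /
   0.66 s) and a ≥ 20 % cross-criterion overlap requirement.
2. **Tick-attachment survival analysis.** Attached-tick counts at
   scheduled checks become per-tick event/censoring records; the
   Kaplan-Meier product-limit estimator
   S(t) = Π<sub>t<sub>i</sub>≤t</sub> (1 − d<sub>i</sub>/n<sub>i</sub>)
   with Greenwood variance and log(−log) 95 % CIs is inverted into a
   removal-probability curve R(t) = 100 × (1 − S(t)); groups are compared
   with the Peto & Peto modification of the Gehan-Wilcoxon test, a
   weighted log-rank test with weights
   w<sub>i</sub> = Π<sub>t<sub>j</sub>≤t<sub>i</sub></sub>
   (n<sub>j</sub> − d<sub>j</sub> + 1)/(n<sub>j</sub> + 1)
   that emphasizes early removal differences.

Around these sit the ancillary quantifications of such studies: the scutal
index (alloscutum length / scutum width, a tick engorgement proxy), Δ
perfusion (laser-speckle ROI minus background over a 20-s time of
interest), hourly bout-count distributions with surprisal in nats,
two-sample Kolmogorov-Smirnov and Mann-Whitney U tests with
exact/permutation options, and a permutation test of group separation in
the (scratch bouts, ticks remaining) plane.

Because live-animal recordings are not redistributable, the package ships
a synthetic-data generator (`iitr.synthetic`) that embeds ground-truth
scratch bouts and behavioral distractors in tracking series and simulates
tick-removal experiments with known piecewise-constant hazards, scheduled
observation, and right censoring. Every stage is tested against that
ground truth and against independent naive re-implementations.

## Worked example

```python
import iitr

# a 1-h session with 6 embedded scratch bouts and 6 distractor epochs
series, truth = iitr.make_session(seed=7, duration_s=3600.0, n_bouts=6,
                                  n_distractors=6, noise=iitr.calibrated_noise())
bouts, audit = iitr.detect_bouts(series)
print(f"embedded bouts: {len(truth)}, validated bouts: {len(bouts)}")

# a two-arm removal experiment: restricted (E-collar) vs unrestricted access
models = [iitr.RemovalModel("restricted", 0.004, censor_h=48.0),
          iitr.RemovalModel("unrestricted", 0.05, censor_h=48.0)]
records = iitr.generate_removal_experiment(1, models, n_animals=7,
                                           ticks_per_animal=13,
                                           observation_times_h=[12, 24, 36, 48])
for label, sub in records.groupby("group"):
    rc = iitr.removal_curve(iitr.km_estimate(sub))
    print(f"{label}: removal at 48 h = {rc.R[-1]:.1f}% "
          f"(95% CI {rc.ci_low[-1]:.1f}-{rc.ci_high[-1]:.1f})")
res = iitr.peto_peto_test(records)
print(f"Peto-Peto: chi2 = {res.statistic:.2f}, df = {res.df}, p = {res.p:.3g}")
```

prints

```
embedded bouts: 6, validated bouts: 6
restricted: removal at 48 h = 15.4% (95% CI 9.4-24.6)
unrestricted: removal at 48 h = 91.2% (95% CI 84.3-95.9)
Peto-Peto: chi2 = 116.14, df = 1, p = 4.44e-27
```

The detector recovered all six embedded bouts with no false positives;
the survival chain estimates the removal probability per arm with its
confidence band, and the Peto-Peto test rejects equality of the two
removal processes — the hazard ratio between the arms was 12.5 by
construction.

A command-line pipeline wraps the same library
(`iitr run --config config.yaml --outdir out`): it simulates a session and
a removal experiment, detects bouts, writes curves, summaries, audit
trails, and a run manifest (config hash, versions, seed) so that one seed
reproduces every output byte-for-byte. See `iitr --help`.

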