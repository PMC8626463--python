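# Methods

## The pipeline

`brushdom` implements a four-stage analysis of dominance and
mechanical-brush use in a dynamically changing group of pre-partum dairy
cows:

1. **Replacement detection** (`brushdom.agonism`). At each feed or
   water bin independently, visits are ordered by start time; a
   replacement is scored for every pair of consecutive occupancies by
   different cows whose gap (next start − previous end) lies in
   [0, 26] s, boundary inclusive. Pairing only consecutive occupancies
   means one departure can produce at most one replacement. No minimum
   visit duration or intake filter is applied. Unsuccessful displacement
   attempts are unobservable in bin data and are not modelled.
2. **Elo rating** (`brushdom.elo`). Ratings start at 1000 on entry,
   are updated per replacement in chronological order (deterministic
   tie-break on time, bin, actor) with transfer `(1 − p)·k`, `k = 20`,
   and winning expectation `p = Φ(ΔR / s)`, the standard-normal CDF with
   scale `s = 200·√2` — the convention of the animal-dominance Elo
   literature. This satisfies every printed constraint of the method:
   `p = 0.5` and a 10-point exchange at equal ratings, expected outcomes
   transferring strictly less than 10 points (reported band 0–9 via
   floor), upsets strictly more (band 11–20 via ceiling). Ratings are
   real-valued; the bands are reporting devices, not rounding inside the
   update. `erfc` is used in the tails so a huge favourite's transfer
   stays strictly positive in floating point.
3. **Selection** (`brushdom.stats.select_extremes`). Each cow whose
   full 7-day pre-calving window is observed gets the mean of her daily
   snapshots over that window (calendar days ending the day before the
   calving day). Cows strictly below the 0.15 or strictly above the 0.85
   empirical quantile (linear-interpolation definition) are eligible;
   the 12 lowest and 12 highest by mean rating form the subordinate and
   dominant focal groups. Excluded cows (health flag) never enter.
4. **Brush statistics** (`brushdom.stats`). One-way random-effects ICC
   of the cow × day brush-minute matrix,
   `(MS_b − MS_w) / (MS_b + (k−1)·MS_w)`; five single-predictor OLS
   models on weekly totals, F on (1, 22) df with 24 focal cows; and
   balanced split-plot ANOVAs of the per-cow mean daily minutes in eight
   3-h periods.

## Conventions and numerical choices

* Timestamps are timezone-naive local barn time at 1-s resolution; all
  durations are computed in seconds and reported in minutes. Days are
  calendar days; an event belongs to the day of its start, and bouts
  spanning midnight (or a 3-h period boundary) are split proportionally.
* **Daily snapshots.** "Updated daily" is implemented as per-event
  updating with end-of-day snapshots. The snapshot recorded for a cow's
  entry day is her rating *at entry* (1000), so the first snapshot
  equals the start rating even when she interacts on her entry day;
  entry-day events are visible from the next day's snapshot on. Exits
  freeze the trajectory. Re-entering cows would be treated as new
  residences restarting at 1000.
* **Diel model.** With 24 focal cows × 8 periods (192 observations) the
  design decomposes into dominance (1 df), cow-within-dominance (22 df),
  period (7 df), period × dominance (7 df) and residual (154 df).
  Period and the interaction are tested against the residual — (7, 154)
  df — and the dominance main effect against the cow stratum (1, 22),
  the correct error stratum for a between-cow factor in a split-plot
  layout. The decomposition is closed-form for the balanced design and
  is verified in the tests against an explicit least-squares projection
  oracle; incomplete or unbalanced designs raise an error rather than
  silently refitting.
* **Degenerate inputs.** A constant predictor or response flags the
  model degenerate (F = NaN) instead of failing; a brush matrix with
  zero total variance flags the ICC undefined; a cow with no snapshots
  in her pre-calving window is flagged missing and excluded downstream;
  a selection tail smaller than the group size raises an error stating
  the counts per tail.
* Weekly displacement counts and brush totals cover the same 7-day
  pre-calving window as the Elo mean. Feeding time counts feed-bin
  visits only. No multiple-testing correction is applied (five separate
  models at α = 0.05).

## The synthetic herd

The generator (`brushdom.simulate`) is an event-driven model of the
pen: 20 resident cows, 12 feed bins, 2 water bins, one brush, fresh
feed at 08:00 and 16:00. Each cow carries a static latent dominance
value, i.i.d. standard normal at entry. Residence lasts ≈ 21 ± 4 days;
on calving the cow leaves and a replacement enters the same day, so
about a hundred cows pass through a 112-day run.

* **Feeding.** Per-cow visit attempts (55/day) follow an hourly
  intensity profile with strong peaks in the hours after each delivery
  and low night activity; visit lengths are lognormal (mean 5.5 min).
  Demand right after delivery exceeds bin capacity, which is what makes
  the feed bunk competitive: a motivated cow finding every bin occupied
  challenges an occupant, succeeding with probability
  `logistic(hierarchy_strength · (latent_actor − latent_reactor))`
  (default strength 5). A success is written into the log exactly as
  the sensors would see it — the reactor's visit ends at t, the actor's
  visit at the same bin starts at t + gap, gap uniform on [2, 20] s —
  so every true replacement is recoverable by the 26-s rule (recall 1
  by construction). A cow who takes a *freely available* bin instead
  walks to it first (approach delay 20–120 s), so voluntary takeovers
  rarely mimic the push signature; measured precision of the detector
  on the generator's logs is ≈ 0.97, with the remaining false positives
  being genuinely coincidental quick successions.
* **Directed aggression.** A challenger sizes up to three visible
  occupants, goes for the lowest-ranking one, and declines the fight
  when her perceived odds through the same logistic fall below 0.38
  (aggression flows down the hierarchy). With a flat hierarchy
  (strength 0) every contest looks winnable and targets cannot be
  ranked, so attacks and outcomes are uniform coin flips. At strength 5
  the latently higher-ranked cow wins > 95% of recorded replacements;
  failed or declined challengers retry after an exponential wait
  (queueing produces realistic visit fragmentation).
* **Brushing.** Bouts arise from a per-cow point process with baseline
  4.5 bouts/day and lognormal durations (mean 6 min). The rate scales
  with `exp(0.45 · latent)` and, for above-median cows only, is
  elevated 2.5× during feeding peaks — this is what produces the
  period × dominance interaction, standing in for the brush's placement
  in the feed alley without modelling pen geometry. A dominance-
  *independent* per-cow lognormal frailty (σ = 0.4) adds the large
  individual variation in brushing seen in real herds. The slope and
  frailty were calibrated once against the reported group moments of
  weekly brush use in pre-partum cows (a ≈ 2.4-fold dominant-to-
  subordinate ratio with within-group CV ≈ 0.5), giving daily
  repeatability (ICC) around 0.65–0.75 and group-level brush occupancy
  of ≈ 5 h/day.
* **Brush displacements.** A group-level Poisson process (3/day,
  daytime) picks performer and recipient uniformly among resident cows,
  independent of dominance by construction — the null the displacement
  models are calibrated against. If the recipient happens to be
  brushing, her bout is truncated and the performer takes over.
* **Determinism.** One seeded `numpy.random.Generator` drives
  everything; dynamically scheduled events carry deterministic
  tie-break keys, so a fixed seed yields bit-identical logs.

### What the generator does not emulate

Lying, drinking time budgets beyond simple water visits, spatial
movement, metabolic state, learning or ageing of dominance, unsuccessful
displacement attempts at the bins, and observer error in brush scoring.
Passing tests therefore show that the pipeline recovers the structures
the generator plants — a latent order expressed through bin competition
and a dominance-linked brushing rate — not that real barns satisfy the
generator's assumptions. Because latent dominance is static and
outcomes steeply ordered at the default strength, hierarchy recovery
here is easier than in herds with bidirectional relationships and
intransitive triads; conversely, a mechanistic side-effect of peak
competition is that subordinates shift some feeding off-peak, which can
surface as a mild diel feeding interaction absent from the real study.

## Problem sizes used in tests and analyses

The default scenario is 60 days (hierarchy-recovery checks: Spearman
between latent dominance and final rating ≥ 0.8 over cows with at least
a week of residence). The percentile selection needs roughly 80+ scored
cows to fill two 12-cow tails at the 0.15/0.85 cuts, so the end-to-end
analyses and the `analysis/` scripts run the same generator for 112
days (~100 scored cows). Seed sweeps use 200 independent 49-day runs
with focal groups taken from the ground-truth latent ranking: 100 seeds
for the directional power of the dominance→brush model (≥ 80%
rejections at α = 0.05 at the calibrated effect size above) and all 200
for the type-I calibration of the displacement models (rejection rate
inside a wide binomial envelope around 0.05). ICC parameter recovery
uses 24 × 7 normal matrices at between/within variance ratios 3:1, 1:1
and 1:4.

## Known limitations

* The expectation function of the original Elo implementation is not
  printed in the source material; the normal-CDF form with scale 200·√2
  is the documented choice here and the scale is configurable.
* The ICC variant is the one-way consistency form on the cow × day
  matrix; two-way forms are not implemented.
* The diel ANOVA requires a complete balanced design; missing cells are
  an error by design, not imputed.
* Proprietary binary sensor exports are out of scope; inputs are the
  CSV schemas documented in `brushdom.io`.
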