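# Methods

This note documents the models, conventions, and design choices behind
`digiphen`: what the synthetic cohort generator emulates, how each
passive phenotype is defined, and which statistical conventions were
fixed so that every number the pipeline prints is reproducible.

## The synthetic deployment

The generator emulates a 4-week, two-arm adolescent cohort (defaults: 19
control + 17 intervention, 28 days) in which each participant carries a
phone that records GPS, screen lock/unlock events, and sleep, answers
EMA prompts, fills a 48-cell lifestyle grid, and completes
questionnaires at three waves (baseline / mid / post).

### Latent daily distress

Each participant carries a latent state `z_c(d)` for each construct
(depression, anxiety, stress), following a stationary AR(1) process with
autocorrelation 0.5 and unit marginal variance around a group-specific
mean (default: intervention arm +0.5 SD on depression and stress,
reflecting the elevated-baseline arm such studies recruit). Day-to-day
fluctuation is deliberate: momentary affect is not a stable trait, and
within-person variation is what EMA exists to capture.

EMA ratings discretize `z_c + noise` (noise SD 1.0) through fixed
symmetric cut-points at z = −1.5, −0.5, 0.5, 1.5 onto the 1–5 ordinal
scale. Each prompt is answered independently with probability
`adherence_p` (default 0.9, matching the ≈90% adherence that motivated
this design).

### Couplings: the ground truth for parameter recovery

The coupling map (construct → feature → signed coefficient) feeds the
latent state into five behavioural knobs, each a clipped linear function
`base + scale·Σ_c coef_c·z_c + noise`:

| knob | base | scale | noise SD | clip |
|---|---|---|---|---|
| nap length (daytime sleep, min) | 35 | 45 | 12 | [0, 100] |
| post-midnight usage (min) | 35 | 35 | 10 | [0, 150] |
| daytime usage (min) | 170 | 45 | 25 | [30, 480] |
| usage episodes per day | 24 | 7 | 2.5 | [4, 60] |
| evening walk distance (km) | 1.5 | 1.2 | 0.4 | [0.9, 6] |

Only these five features are accepted as coupling targets; location
variance and entropy emerge from the movement kinematics and cannot be
steered without also moving travel distance, so the config validator
rejects them rather than silently failing to realize them. Default
coefficients are weak (|coef| 0.03–0.08) with signs chosen so the
default cohort reproduces the weak-correlation regime typical of
observational smartphone-sensing studies (pooled |r| ≈ 0.07–0.2 over
~1000 participant-days): higher distress goes with more daytime sleep
(depression/anxiety), less late-night phone use, fewer unlocks, and
shorter travel. Note that derived features inherit couplings
mechanistically — e.g. total sleep contains the nap, and nighttime sleep
onset is delayed by post-midnight phone use — so a single injected
coupling surfaces in several correlated grid cells, as it would in real
data.

### Daily routine and raw streams

Days follow a school-week template over configurable anchor places:
home overnight, school 08:30–15:30 on weekdays (lunch break 12:00–13:00),
tutoring 18:00–20:00 on Mon/Wed/Fri, an evening (weekday) or afternoon
(weekend) out-and-back walk at 4.5 km/h, and linear-interpolated transit
between anchors at ~2.5–4 km/h. GPS is sampled on a regular grid
(default every 10 min; Monte-Carlo tests use 20 min) with Gaussian
jitter of `gps_noise_m` (default 20 m).

Sleep: nightly onset ≈ 23:20 (SD 12 min) — or, on nights with
post-midnight phone use, a few minutes after that usage ends — until
≈ 07:05 (SD 12 min), plus an afternoon nap when the nap knob exceeds
8 min. Screen episodes alternate strictly: an optional post-midnight
session, a session just after waking, daytime sessions placed near the
centres of equal slots across waking hours (so inter-pickup gaps rarely
exceed the 60-min sleep-inference threshold — phones are in fact picked
up at a fairly steady rhythm), and a final session shortly before sleep
onset. This pre-bed/post-wake structure is what makes screen-gap sleep
inference work on real phones, and the generator reproduces it; inferred
vs true daily sleep totals agree to ≈9% mean absolute relative error at
default noise.

Questionnaires are generated **per item** and then scored by the same
scoring code the analysis uses: DASS-21 (21 items, 0–3, three 7-item
subscales with the standard item allocation), self-efficacy (22 items,
1–5), time management (30 items, 1–5), and MAUQ (21 items, 1–7,
intervention arm at post only). Item responses are
`clip(round(N(target/n_items, 0.7)))` with a per-instrument person
random effect (SD 1.5 score units) held constant across waves — this
induces the wave-to-wave correlation a repeated-measures design needs.
Default group×time shifts are calibrated so baseline-to-post change
effects land at Cohen's |d| ≈ 0.3–0.5 (small-to-moderate), with anxiety
declining equally in both arms (time effect without interaction).

All randomness descends from one root `SeedSequence(seed)` with one
spawned substream per participant: identical configs give byte-identical
datasets, and participants can be generated independently.

### What the generator does *not* emulate

Realistic human mobility (Lévy flights, exploration), weather and school
calendars, GPS dropouts and urban-canyon multipath, app-level usage,
notification fatigue, informative missingness (adherence is independent
of distress), and the semantics of mood adjectives. Passing tests
therefore demonstrate that the pipeline recovers what this generative
family injects — not that real adolescent data obey these models.

## Passive phenotype definitions

- **Speeds** are first differences of position over time
  (haversine distance, Earth radius 6371.0 km). An interval is
  *stationary* iff speed < 1 km/h; exactly 1 km/h counts as moving
  (the boundary is unstated in common practice; fixing it strictly
  makes the rule deterministic).
- **Significant places**: K-means over stationary points in raw lat/lon
  degrees (adequate at neighbourhood scale), k chosen as the smallest
  value (cap 10) whose maximum great-circle point-to-centroid distance
  is below 500 m — a coverage-radius rule mirroring common
  significant-place practice. The dwell time of a stationary interval is
  attributed to the cluster of its leading point. No stationary points
  gives the empty sentinel (k = 0, entropy 0).
- **Location variance** is `ln(var(lat) + var(lon) + 1e-10)`; the small
  floor keeps motionless days finite while preserving monotonicity in
  spread.
- **Day/night boundaries** are half-open: daytime [07:00, 23:00),
  nighttime the complement — no minute is counted twice. Sleep and phone
  features share these boundaries, and intervals spanning midnight are
  clipped to calendar dates before summation, so daily aggregates are
  exact partitions.
- **Sleep inference from screen logs**: screen-off gaps ≥ 60 min
  overlapping the nightly [21:00, 11:00) window are nighttime sleep
  candidates; gaps ≥ 60 min lying entirely within [12:00, 18:00) are
  naps. Real sleep records, when available, are used directly.
- **Phone features**: one episode per unlock→lock pair; a day beginning
  or ending mid-episode is closed at the day boundary, so
  usage + lock = 1440 min on every fully observed day. Unlock count is
  the number of unlock events on the date.

## EMA engine

Eight prompt contexts; at most one prompt per slot per day, drawn
uniformly within the slot's eligible window after subtracting the merged
exclusion windows (school minus lunch, tutoring, sleep). Slot windows
are parameterized with defaults (waking = wake + 30 min; lunch
12:00–13:00; after school = 2 h; around tutoring = 1 h; before bedtime
= 1 h). The post-midnight slot fires at the instant cumulative usage
since 00:00 crosses 30 min, if that instant is eligible. Because the
conditional slot may or may not fire, adherence denominators count
prompts actually sent rather than a fixed daily number. Any response
logged before the next prompt is treated as valid (no expiry is
modelled).

## Statistical conventions

- **Quartiles** by linear interpolation of order statistics (so the
  worked fence example [1..9, 100] → Q1 = 3.25, Q3 = 7.75, fences
  −3.5/14.5 is exactly reproducible). Values outside 1.5 × IQR are
  excluded and logged; missing values are never imputed.
- **Correlations** pool all participant-days into a single coefficient
  per feature × construct cell, mirroring the one-coefficient-per-cell
  presentation such studies use; a within-person-centered variant and a
  Benjamini–Hochberg column exist but are off by default (α = .05 per
  cell is the default inferential rule).
- **Mixed 2×3 ANOVA** (group between, wave within) assumes sphericity —
  no Greenhouse–Geisser correction — which yields the integer df
  convention ((2, 68) for the interaction at N = 36) these studies
  print. F and p come from `pingouin.mixed_anova`; the package's own
  split-plot sum-of-squares partition (tested against a definitional
  brute-force oracle) supplies the error terms for Scheffé post hoc
  contrasts, which by construction cannot reject unless the omnibus F
  is significant. Participants missing a wave are listwise-deleted and
  logged.
- **Cohen's d** is defined on baseline-to-post change scores:
  (mean change intervention − mean change control) / pooled change SD.
  The exact formula behind published d values is often unstated; this
  choice is declared here and used consistently.
- **Mann–Whitney U** is reported as min(U₁, U₂) with the
  normal-approximation p (tie-corrected).
- **Power / sample size** uses the noncentral F with the standard
  repeated-measures noncentrality adjustments — between-group effects
  scaled by 1/(1 + (m−1)ρ), within/interaction by 1/(1−ρ) — and returns
  the smallest per-group n whose power reaches the target. The effect
  family and the repeated-measures correlation ρ are explicit
  parameters: a published "effect size 0.33 → 26/group" is reproduced
  by the between family at ρ = 0.5, but the calculator does not guess a
  family on the caller's behalf.

## Numerical and engineering choices

- Day/night segmentation runs on integer nanoseconds, so
  daytime + nighttime equals the interval duration to machine precision.
- K-means uses k-means++ with `n_init = 10` for ≤ 10 points (where the
  exhaustive-enumeration oracle requires the global optimum) and 1
  otherwise; per-day clustering seeds derive from CRC32 of
  (seed, participant, day), keeping extraction deterministic and
  parallelizable.
- Monte-Carlo suites run on reduced cohorts chosen to keep a single-CPU
  run short while leaving ample statistical margin: the null type-I
  check uses 50 seeds × (8 participants × 14 days), the −0.4
  coupling-recovery check 100 seeds × (8 × 28), both at 20-min GPS
  sampling. At these sizes the injected −0.4 coupling yields pooled
  r ≈ −0.6, so the ≥90% recovery criterion is met with a wide margin.
- The 24 h bound on a single sleep record is enforced at record
  validation, not on merged unions (overlapping records may legitimately
  union to more).

## Known limitations

- Clustering in raw degrees slightly distorts east-west distances at
  high latitudes; irrelevant at the city scale simulated here.
- The coverage-radius k-selection rule can split one genuinely large
  place (e.g. a campus) into two clusters; entropy then counts both.
- Item-level clipping compresses instruments whose targets sit near the
  response ceiling (the elevated-baseline arm's DASS items), attenuating
  generated effect sizes somewhat below their nominal calibration.
- Pooled correlations mix within- and between-person variance; the
  within-person toggle exists precisely because the pooled coefficient
  should not be read as a within-person effect.
- Adherence is missing-completely-at-random; real missingness is likely
  informative.
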