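# Methods

`circalight` analyses a 16-week baseline/intervention lighting study in a
residential dementia-care setting: four weeks of static lighting (baseline),
then twelve weeks of a dynamic, daylight-mimicking program, analysed as a
midpoint (weeks 5-10) and an end-of-intervention (weeks 10-16) phase. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic cohort does and does not emulate.

## Phase plan

The printed week ranges share week 10; `PhasePlan` uses half-open ranges
[1, 5), [5, 10), [10, 17) so no week is double-counted — week 10 belongs to
the final phase only. The calendar anchor (default Monday 2023-03-06) only
affects labels and daylight-saving handling; all clock windows (night,
sundowning) are evaluated in local civil time, so DST transition days are
23- or 25-hour days with their actual epochs.

## Sensing model (ingest)

Radar frames are per-resident positional samples, nominally 8 Hz while the
resident is in a sensored room. The per-epoch activity measure is the summed
Euclidean x-y displacement of consecutive frame pairs over clock-aligned
15-minute epochs:

* a pair is credited to the epoch containing its *later* frame, so no
  displacement is lost at boundaries;
* pairs separated by more than the absence-gap threshold (default 60 s) are
  discarded — the jump across an absence is not observed movement;
* epochs with no frames are missing (NaN), never zero: absence of evidence
  of movement is not evidence of rest.

Raw epoch totals are normalized to percent activity by the **running maximum
epoch total** seen so far for that resident (`mode="running_max"`). The
running max stabilizes once the resident's most active quarter-hour has been
observed; analyses therefore drop a configurable burn-in (default 1 day). A
`global_max` mode (normalize by the series-wide maximum) is available for
retrospective batch analysis. Normalizing each epoch by its own maximum
would return 100% everywhere, so no such mode exists.

Occupancy uses presence runs: consecutive frames closer than the gap
threshold define presence intervals, intersected with the epoch grid.

## Rest-activity metrics (circadian)

The standard nonparametric triple on hourly-binned activity
(within-hour means of the 15-minute series, hours with <50% epoch coverage
dropped, counts adjusted):

* **IS** (interdaily stability) = N·Σ_h(x̄_h − x̄)² / (p·Σ_i(x_i − x̄)²),
  p = 24: the fraction of variance explained by the average 24-hour
  profile; 1 for a perfectly repeated day, undefined (NaN) for a constant
  series.
* **IV** (intradaily variability) = N·Σ(x_i − x_{i−1})² / ((N−1)·Σ(x_i − x̄)²),
  computed over truly consecutive hour pairs only (gaps contribute no
  pairs; the ratio uses mean squared successive difference over variance,
  which reduces to the textbook formula on complete data). Typical human
  data lie in 0-2; the mathematical supremum is 4, attained by strict
  alternation, and the implementation does not clamp.
* **RA** = (M10 − L5)/(M10 + L5) on the phase-average 24-hour profile, with
  M10/L5 the best consecutive 10-/5-hour windows (wrapping midnight).
  Computing M10/L5 on the average profile (rather than per-day) is the
  common convention; it requires a complete 24-hour profile.

Sundowning is proxied by mean activity in the 4 hours before sunset, with
sunset configured per phase (20:00 / 21:00 / 22:00 by default, matching the
study months) rather than computed from an ephemeris. Because each phase
uses a different clock window, phase contrasts of this proxy compare
different parts of the diurnal profile by design; it is reported alongside,
not pooled with, the rhythm metrics, and it is excluded from type-I-error
evaluations of the pipeline (its null is not "no difference").

## Sleep metrics

Nights are scored in a 22:00-08:00 local window (configurable; wake times
past 08:00 are accommodated by extending the window). Rest onset is the
start of the first run of ≥ `min_run` epochs at or below threshold θ; rest
offset is the end of the last such run; a night with no qualifying run is
unscored and excluded from medians. Disturbances are maximal runs above θ
inside the rest period lasting ≥ `min_bout` epochs; total sleep = rest span
− summed bout minutes (an exact identity, tested). Defaults θ = 10%
activity, min_run = 4 epochs (1 h), min_bout = 1 epoch (15 min) — declared
configuration, not constants.

Consequences worth knowing: movement before the first qualifying quiet run
reads as sleep-onset latency, not a disturbance, so bouts at the window
edges are systematically excluded — the detector counts *within-rest*
disturbances. Scheduled night-time care checks can register as genuine
bouts; no correction is applied. Whether a bout is a movement bout or a
bed-exit cannot be distinguished from activity alone; movement bouts are
what is counted.

Aggregation uses medians (per resident over nights, then over residents),
which resist the strong skew of count data in small cohorts; a leave-one-out
option supports sensitivity reanalysis (e.g. excluding a resident on
sleeping medication).

## Lighting model

The dynamic program is a fixed daily schedule of (illuminance, CCT, drive)
blocks; lookups hold the nearest block's values outside the listed range
while lights are on. Because the luminaire spectrum is fixed, melanopic
quantities are scalar transforms of photopic lux:

* melanopic EDI = lux × melanopic ratio (default 331/260 ≈ 1.273, anchored
  on the program's 260-lux setpoint);
* circadian stimulus via the Rea saturation model
  CS = 0.7·(1 − 1/(1 + (CL_A/355.7)^1.1026)), with CL_A = lux × cl_a_per_lux
  anchored by closed-form inversion of the model at the same setpoint
  (CS 0.404 at 260 lux ⇒ CL_A/lux ≈ 1.814).

A single anchored scalar cannot be exact at every setpoint because the
program's CCT (hence spectrum) varies through the day: the anchored model
reproduces CS 0.431 at 300 lux to print precision and leaves a ≈0.002
residual at 550 lux/6500 K. Full spectral integration (CIE S 026 action
spectra, two-channel circadian-light opponency) is out of scope; both
anchors are configuration.

Exposure analysis: time away from the sensored rooms is attributed to common
areas, which run fully dynamic lighting during the intervention phases, so
dynamic exposure = (present ∧ lights on) + (absent); the baseline phase is
0% by definition. Within an epoch, presence and switch-state fractions
combine multiplicatively — exact whenever the lights do not toggle inside a
15-minute epoch.

## QUALIDEM scoring

Weekly proxy-rated item responses are summed per subscale after
reverse-coding negative-worded items, so larger is always better. The
item-to-subscale map is an editable YAML (the shipped default follows the
37-item instrument: A 7, B 6, C 3, D 3, E 3, F 6, G 3, H 4, I 2 items,
ratings 0-3, subscales C/D/G reverse-coded, plus three unscored research
items on J). Subscales with at least two thirds of items answered are
prorated to the full item count; below that they are flagged missing.
Subscales I and J are scored and reported but excluded from statistics.

## Statistical protocol

All contrasts are paired within resident. Shapiro-Wilk on the paired
differences (α = 0.05, an assumed level) gates the branch: paired t test
(two-tailed) with Cohen's d_z = mean(diff)/SD(diff) — the matched-pairs
convention; an averaged-SD variant is available — or Wilcoxon signed-rank
(exact null for n ≤ 25, normal approximation with continuity correction
above, zero differences dropped) with Cliff's δ. Specific endpoints can be
forced nonparametric regardless of the gate (the default config forces
subscales E and H). Constant nonzero differences leave the t statistic
undefined and are flagged; identical vectors return p = 1 with zero effect.
Raw p values are reported across endpoints (no multiplicity correction, by
design); a Holm option exists but is off by default.

Effect-size bands: Cohen's d at 0.2/0.5/0.8; Cliff's δ at 0.147/0.33/0.474,
with magnitudes between the first two cut-offs labelled "high overlap".
Sample-size planning finds the smallest n at which the two-tailed paired t
test with noncentrality √n·d reaches the requested power, via the
noncentral t distribution (d = 0.5, α = 0.05, power 0.80 ⇒ n = 34).

Per-resident per-phase values aggregate weekly well-being scores and
rhythm metrics by mean and nightly sleep counts by median (configurable);
how weekly scores were paired into phase values is not externally
specified, so the phase mean is a documented package choice surfaced in
config.

## Synthetic cohort

No deposited sensor data exist, so a seeded generator produces cohorts with
known ground truth:

* **Activity**: clipped cosinor, activity = clip(mesor + amplitude·cos(2π(t −
  acrophase)/24) + N(0, σ), 0, 100) per epoch. Defaults: mesor 30%,
  amplitude 45%, acrophase 15 h, σ = 3%. The amplitude deliberately exceeds
  the mesor: clipping at zero produces a ~8.5-hour quiet nocturnal plateau
  (below the sleep threshold θ = 10) — without it the generator does not
  actually exhibit nocturnal rest. Disturbances: per night a Poisson count
  (default mean 1.5) of bouts starting uniformly in the bed window
  (22:00-07:00), exponentially distributed durations (mean 20 min, ≥1
  epoch), elevated activity U(40, 90)%.
* **Presence**: two-state semi-Markov process (exponential dwells, present
  mean 60 min, absent mean solved from the target occupancy fraction,
  default 0.7), with forced presence during the bed window.
* **Frames**: emitted only while present. `sparse` mode (default) emits one
  frame per 45 s and spreads each epoch's target translation evenly over its
  retained frame pairs — epoch totals and presence runs are preserved
  exactly at a tractable volume (a 16-week, 11-resident cohort is ~2M rows;
  continuous 8 Hz would be ~10^9). `burst` mode adds an 8 Hz movement burst
  per epoch for realism on short spans. An epoch-level fast path skips frame
  emission entirely and is what the Monte-Carlo test campaigns use.
* **Switch log**: lights turn on at presence-session start with probability
  `lights_on_given_present` (default 0.9) outside the bed window, off at
  session end.
* **QUALIDEM panel**: per-resident subscale latent means (base 1.8 on the
  0-3 rating scale, resident SD 0.3) drift week to week (SD 0.25); item
  responses are rounded, truncated normals around the latent (item SD 0.6),
  emitted pre-reversal for reverse-coded items.

**Effect injection** happens in metric space at phase boundaries: an RA
effect re-solves the cosinor amplitude (Brent root-finding) so the RA of the
generator's *expected* activity profile — disturbance regime included —
shifts by exactly the requested delta; an IS effect rescales σ via
IS ≈ V24/(V24 + σ²/4); a sleep effect shifts the nightly Poisson mean; a
QUALIDEM effect shifts the subscale latent by delta week-level SDs. Solving
against the expected profile rather than the bare cosinor keeps recovery
unbiased in the presence of disturbances; residual attenuation from noise
clipping at the zero floor and from extremum selection in M10/L5 is small
relative to Monte-Carlo spread and is covered by the recovery tests'
interval assertions.

**Seeding**: resident k derives its streams from `SeedSequence([master, k])`
split into independent children (noise, disturbances, presence, switches);
the panel uses `SeedSequence([master, 100000 + k])`. Identical seeds give
byte-identical datasets.

**What the generator does not emulate** — and hence what passing tests do
not show about real deployments: radar dropouts and multipath artefacts,
multi-person rooms and visitor contamination, care-staff check-induced
bouts, seasonally drifting sunset, rater bias and missingness patterns in
proxy questionnaires, and day-to-day behavioural nonstationarity beyond the
injected effects. Parameter-recovery results certify the pipeline's
internal consistency, not field accuracy.

## Problem sizes and numerics

Monte-Carlo campaigns in the test suite use a scaled 9-week two-phase plan
(4-week baseline, 4-week intervention, 1-week tail) with 11 residents, 200
replicates for recovery/power comparisons, 100 seeds for per-endpoint
type-I checks, 2,000 draws for the gate-level size check, and 10,000 draws
for the disturbance-count oracle; campaign results are cached so module and
acceptance tests share one run. Root-finding uses `scipy.optimize.brentq`
(xtol 1e-10); the CS inverse is closed-form and round-trips to 1e-9.
Degenerate inputs are flagged rather than guessed: zero-variance series give
NaN metrics, unscored nights propagate as missing, and subscales below the
proration threshold are NaN.

## Known limitations

* The melanopic pathway is anchored, not spectrally integrated; anchors are
  only as good as the setpoint they come from (see the 550-lux residual).
* The sundowning proxy confounds clock window with phase by construction.
* Sleep-bout counts measure within-rest movement runs; bouts at the rest
  boundary are attributed to sleep latency / wake, and bed-exits are not
  distinguished from in-bed movement.
* Running-max normalization makes early epochs incomparable across
  residents until each resident's maximum has been observed (hence the
  burn-in).
* The generator's cosinor-plus-bouts model is the simplest structure that
  reproduces IS/IV/RA behaviour; it is not an estimate of any real cohort.
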