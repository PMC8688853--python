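# Methods

## The biomarker model

Scheduled breathalyzer monitoring produces, per patient and day, a set of
test outcomes: performed with a breath alcohol content (BrAC), or omitted.
BrAC is converted to a blood alcohol equivalent by the standard factor
BAC = 2.0 × BrAC (both in ‰). A performed test counts as *drinking* when
BAC ≥ 0.05 ‰; this threshold sits just above the level of quantification of
the measurement population, LOQ = median + 10·IQR (0.006 + 10 × 0.004 =
0.046 ‰), so that median statistics — robust to a minority of drinking
measurements — define the noise floor.

Each scheduled test is scored in [0, 1]:

| outcome | score |
|---|---|
| performed, BAC < 0.05 ‰ | 1 |
| performed, BAC ≥ 0.05 ‰ | 0 |
| omitted, streak of k consecutive omissions | max(0, 1 − k/K) |

with K = tests-per-day × 48 h / 24 h, so an omission streak reaches the
positive-test weight exactly when it spans 48 hours of scheduled testing. A
positive test therefore immediately receives the full negative weight, while
omissions accumulate it gradually — drinking is detectable both from alcohol
in performed tests and from the omission pattern. The linear decay shape is
the minimal choice consistent with a per-test lowering and the 48-h endpoint;
only the endpoint is externally constrained, and the shape is a configurable
strategy in principle. Streaks span day boundaries and reset on any performed
test, sober or positive.

The daily raw score x_t is 100 × the mean of the day's per-test scores —
the mean keeps days with different scheduled counts on a common 0–100 scale.
The Addiction Monitoring Index is the exponentially smoothed series

    s_0 = x_0,    s_t = α·x_t + (1 − α)·s_{t−1}

with no burn-in. AMI-N denotes α = N/100: AMI-6 is a slow baseline (mean
memory ≈ 16 days), AMI-21 the conventional therapist-facing index, AMI-45 a
fast tracker. The smoothing is delegated to `pandas.Series.ewm(alpha,
adjust=False)`, which implements exactly this recurrence; the test suite
verifies it against the independent weighted-sum closed form to 1e−9.

Missing whole calendar days between a patient's first and last monitored day
are expanded to all-omitted days under the configured (or modal observed)
schedule, so the AMI decays during device silence rather than pausing.

**MTBT** (maximum time between tests) is the longest interval between
consecutive performed tests attributed to a day; an interval is attributed to
every calendar day it intersects, so each day inside a multi-day silence
carries the full gap length and per-patient MTBT means can far exceed 24 h.
Gaps to the monitoring-period boundaries are not counted (enrollment day is
not penalised); days intersected by no between-test gap report a missing
MTBT, and a patient with no performed tests at all gets the full monitored
span with a warning. A consequence of the boundary rule: deleting an interior
performed test can only lengthen the gap covering a day (MTBT is monotone
under interior deletions), but deleting the first or last test removes an
uncounted boundary gap and can lower or clear a day's value.

## REI and exacerbation events

REI_t = AMI-45_t / AMI-6_t. Because smoothing weights are strictly positive,
the denominator vanishes only when the entire raw history is zero, in which
case the numerator is zero too; that 0/0 day is defined as REI = 1 (a
patient at a constant level, however low, is trendless). Values are capped
at 10: after a deep dive followed by rapid recovery the raw ratio explodes
upward, and the cap stabilises plots and threshold scans without touching
the sub-threshold region that defines events.

An exacerbation event is a maximal run of consecutive days with REI
*strictly* below the threshold (default 0.8); a day exactly at the threshold
is outside. Events carry their length and the distance from the previous
event's end to their own start (undefined, and excluded from means, for the
first event). Patient summaries report treatment days, %EE (share of
monitored days inside events), event count, mean/max length, mean distance,
and AMI-21/MTBT/DDD/PEth means; a minimum-event-length filter (display
convention 2) suppresses single-day events when wanted.

## Threshold selection scan

For each candidate threshold on a grid (default 17 equally spaced values on
[0.05, 1.1]), days carrying a drinks-per-drinking-day (DDD) observation are
labelled by event membership and the mean DDD difference between the two bins
is summarised by the ANOVA F-ratio — one-way, and two-way with patient as a
categorical fixed factor (main effect only). Both models are fitted by OLS
(`statsmodels`) with type-II ANOVA tables. Thresholds leaving a bin empty
report a missing F rather than failing. The recommendation is the
F-maximising threshold (patient-factor model preferred, ties broken toward
the smaller threshold), reported together with the plateau of thresholds
whose F stays within 80% of the peak. No multiplicity correction is applied
across the grid; the test suite instead demonstrates on null data that
picking the maximal F inflates the winning threshold's apparent significance.
Whether zero-DDD (sober) days enter the scan is a property of the input
table; the simulator reports a mix of positive and zero DDD observations.

## Periodicity analysis

Day-level in-event indicators are analysed against weekday, ISO-8601 week
number, and 30-day treatment bins covering days [0, 390). Per-level %EE with
a 95% Wald interval on the day-level proportion serves visualisation only.
Inference uses logistic regression of the indicator on the factor with
patient-clustered sandwich covariance — the "repeated measures by patient"
design realised without modelling the correlation structure (a GEE with
exchangeable correlation is the natural alternative and gives similar
answers; the sandwich route was chosen as the default for robustness to
misspecification). The joint factor test applies the Hotelling-style
small-sample correction, F = (G−q) W / (q (G−1)) on F(q, G−q) for G patient
clusters and q constraints: the uncorrected multi-df cluster Wald test
over-rejects at moderate G (≈13% observed at G = 30, q = 6, versus ≈8% after
correction at nominal 5%). With G ≤ q the correction is undefined and the
asymptotic chi-square reference is used with a warning. Levels with all days
in (or all out of) events are separated in the likelihood and are dropped
from the fit with a warning.

## Synthetic cohorts

The simulator generates the study conditions the analyses expect: 2–5
scheduled tests/day in 1-h windows (08:00–20:00), omission behaviour
correlated with drinking, BrAC magnitudes around the 0.05 ‰ BAC threshold,
weekday/holiday/treatment-time effects, and multi-day episodes. Daily
drinking follows a logistic model,

    logit P(drink) = base + weekday + ISO-week + ramp(t) + gain·z_{t−1},
    z_t = ρ·z_{t−1} + (1 − ρ)·drink_t,

where ρ (`episode_persistence`) sets the episode time constant and the gain
its self-sustaining strength. Five archetypes cover the qualitative range of
clinical courses: `abstinent` (base logit −12), `controlled` (moderate, mild
weekend preference), `weekend_binger` (+2.5 weekend logits over base −3.5,
weekend/midweek drinking ratio ≈ 9), `periodic_heavy` (ρ = 0.9, gain 4 —
week- to month-long episodes, holiday-week elevation, treatment-time ramp)
and `chaotic` (high base rate, poor compliance throughout). Drinking days
draw DDD ~ lognormal and place above-threshold BACs at 1+ evening windows;
sober tests draw lognormal BrAC noise with BAC median ≈ 0.006 ‰ and IQR
≈ 0.004 ‰, matching the LOQ arithmetic. Omission is Bernoulli per window
(default 5% sober, 15–50% on drinking days by archetype). A pseudo-PEth is
the 21-day moving average of daily drinks × 0.08 µmol/L per drink/day plus
Gaussian noise — it reproduces the qualitative cumulative-intake ordering
across patients, not assay values. DDD is reported on 90% of drinking days
and, as a zero, on 30% of sober days.

Per-patient randomness derives from the master seed via
`SeedSequence(master, spawn_key=(patient_index,))`, so cohorts are
reproducible patient-by-patient.

What the simulator does *not* emulate: within-day pharmacokinetic BAC
curves (threshold-crossing values are placed directly at test windows, which
suffices for an algorithm consuming per-test outcomes), device measurement
artefacts, dropout/re-enrollment, deliberate test-avoidance strategies
beyond the drinking–omission coupling, and real holiday calendars beyond a
few elevated ISO weeks. Passing tests therefore show that the algorithms
behave correctly under controlled, plausibly structured inputs — not that
real cohorts have these effect sizes.

## Calibration studies and problem sizes

Monte Carlo checks of the periodicity test use a direct patient-random-
intercept Bernoulli generator (`simulate_ee_table`: base logit −1.5, patient
SD 0.8) so the weekday odds ratio is controlled exactly: 100 null replicates
at 30 patients × 120 days for the type-I error (target 5% ± 3%), and 100
replicates at 50 patients × 180 days with a weekend odds ratio of 4 for
power (≥95% rejection). The threshold-scan shape check runs the full
pipeline on a 50-patient × 180-day weekend-binger cohort; the acceptance
script uses a 40-patient × 180-day mixed cohort. These sizes give stable
Monte Carlo estimates at desk scale while exercising every code path.

## Numerical and edge-case conventions

- Treatment days are 0-based; all ranges half-open except event start/end
  days, which are inclusive indices into the day series.
- Performed-at timestamps must lie within their window; windows of one
  patient may not overlap; logs must be sorted by patient then window start.
- Oracle equivalences are asserted to 1e−9 (smoothing, REI level
  invariance) and 1e−6 (ANOVA F vs explicit sums of squares).
- Validation failures raise `amirei.ValidationError`; the CLI maps it to
  exit code 1, internal errors to 2.

## Known limitations

- The omission-imputation decay is linear by construction; the production
  systems that inspired this design may use tabulated weights, so absolute
  AMI values are comparable only within this implementation.
- The Wald %EE intervals ignore clustering and undercover when patients are
  heterogeneous; they are drawn for display, with inference delegated to the
  cluster-robust test.
- The threshold scan's argmax is selection-biased (documented, not
  corrected); its recommendation should be read together with the plateau.
- MTBT for days before the first or after the last performed test is
  undefined rather than extrapolated.
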