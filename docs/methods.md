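# Methods

This note records the modelling choices behind `resilmilk`: what is
estimated, how, with which defaults, and where the design was genuinely
open.

## Data model and eligibility

The unit of analysis is one first-parity lactation: an ordered series of
(DIM, DMY) pairs, DIM counted from calving (day 0), DMY in kg/day. Breed
composition is carried in eighths, the resolution used in cattle herdbook
records. A lactation enters the analysis only if it has

* ≥ 100 recorded daily values ("days of data", not calendar span),
* its first record within 5 days of calving,
* no run of more than 5 consecutive missing days between the first and
  last record (trailing truncation from dry-off or culling is not a gap),
* a first calving in 2010 or later.

Zero-yield days are kept: a zero is data, and may be part of a
perturbation. Duplicate (animal, DIM) rows keep the first occurrence;
duplicates and malformed rows are counted and logged rather than silently
dropped.

## Lactation curves

**Wood curve.** `DMY = a·DIM^b·e^(−c·DIM)` fitted by least squares on all
observed days with DIM ≥ 1. Initialisation is the ordinary least-squares
solution of the log-linearised model on positive-yield days, refined by a
bounded trust-region solver with an analytic Jacobian (bounds a > 0,
|b| ≤ 5, 0 ≤ c ≤ 1). There are no random restarts, so the fit is a pure
function of the data. Curve geometry: the peak sits at DIM = b/c, clipped
to [1, 305]; cumulative yields are daily sums over days 1–50 and 1–305,
matching the daily sampling.

**Expected curve.** A quartic polynomial in DIM fitted on days 11–340 by
minimising the pinball loss at τ = 0.7. The minimisation is solved exactly
as a linear program in its dual form (box-constrained, one variable per
observation) with the deterministic HiGHS solver; the fractional dual
variables identify the interpolated observations, from which the
coefficients follow. Degenerate vertices (e.g. data lying exactly on a
quartic) fall back to the primal split-residual LP. For numerical
conditioning the polynomial is fitted in x = DIM/340 and converted back
exactly. Predictions are clipped at 0 kg, since a quartic can go negative
outside its support. τ = 0.7 rather than the median because perturbations
pull yields *down*: a quantile above the median tracks the undisturbed
level. A consequence worth remembering: about 70 % of observed days lie
on or below the curve even for a perfectly healthy cow.

## Perturbation definition

A candidate episode is a maximal run of ≥ 5 consecutive *observed* days
with negative expected-curve residuals; a missing day breaks the run.
The run counts as a perturbation only if yield drops below **85 %** of the
expected level on at least one day, and is **major** if it also drops
below **70 %** at least once, otherwise minor. Two thresholds are
necessary: with a τ = 0.7 curve, shallow ≥ 5-day negative runs are routine
(they are counted separately, as the feature ExpNeg_5d), so a perturbation
count without a depth floor would be dominated by ordinary noise and would
carry the same information as ExpNeg_5d — whereas the two are distinct,
oppositely-behaving quantities. The 70 % severity split mirrors the
ExpPercLower70 feature.

Within an episode the deepest day is the earliest day of maximum deficit;
development runs from the first day through the deepest day, recovery from
the day after the deepest day to the last (so dev + rec = duration). Milk
loss is the summed daily deficit in kg; PertDeepest is the deepest daily
deficit (in kg, not relative) of the episode with the largest loss.
Aggregates over an absent class (e.g. no major episodes) are 0, not
missing, keeping downstream regressions complete-case.

Residuals within ~1e-6 kg of the curve are treated as "on" the curve:
the LP fit interpolates several observations exactly, and float jitter at
1e-9 kg must not register as deficit days.

## The 40 features

Six categories sized 6/6/4/11/11/2. Category 1 is the Wood geometry
(peak yield and DIM, slopes to/after peak, cumulative yield to day 50 and
day 305 — the stated "first 50–305 days" is implemented as those two
endpoints). Category 2 summarises Wood residuals (variance, lag-1
autocorrelation, skewness, max |r|, mean |r|, RMSE — RMSE completes the
six). Category 3 is the expected-curve geometry, with persistency =
(value@305 − value@200)/105 kg/day. Category 4 summarises expected-curve
residuals (RMSE, R², mean |r|, skewness, most negative residual, mean
residual, % negative days, % days below 85 % and below 70 % of expected,
count of ≥ 5-day negative runs, count of residual sign changes). Category
5 is the perturbation block (counts total/minor/major, mean development
and recovery days per class, milk losses per class and total, deepest
deficit). Category 6 holds the resilience indicators LnVar = ln(sample
variance of expected residuals) and ExpAClag1, the lag-1 autocorrelation
in which only pairs of truly consecutive days contribute to the cross
term. Sample statistics use ddof = 1.

## Cohorts

Purebred: ≥ 7/8 of one breed. Crossbred: exactly 4/8 HOL and 4/8 of one
other known breed. Everything else is "other" and excluded from the breed
contrast. The dominant purebred-HOL group is thinned with a deterministic
sort-and-stride scheme: four rounds over (age at first calving, average
DMY, calving date, maximum yearly herd size), each round sorting the
remaining pool (stable, ties by id), taking indices round(i·n/k) for
i = 0..k−1, and removing the selections — covering each trait's range
without randomness. Herd groups: herds of 50–300 cows with mean HOL
fraction < 0.50 (SEL50) or ≥ 0.99 (SEL99); surplus SEL99 herds are thinned
with the same scheme over herd-level traits.

## Statistical analysis

Features and the average-DMY covariate are min-max standardised per
analysis (global within each subset). Breed-proportion covariates enter
as 1 for a purebred, 0.5 for the HOL crossbred of that breed; purebred HOL
rows are all-zero so the intercept is the HOL baseline. The heterosis
indicator is included only when crossbreds are present (it is degenerate
otherwise). Cook's distance uses the printed 1/n mean squared error, not
1/(n−p); the removal takes the top round(0.005·n) distances in a single
pass, then the model is refitted. If the removal strips all variation
from a sparse term (a breed with a handful of cows — exactly the
high-leverage rows the filter targets), that column is dropped from the
refit with a log entry. Significance is strict: p < 0.00125. Summaries
report, per contrast term and feature category, the percentage of
features with a significant coefficient.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as plausible for first-parity dairy cows:

* **Yield levels**: per-breed mean-DMY targets (HOL 27.2, MRY/MON 20.4,
  JER 18.1, SIM 22.3, DFR 21.0, BSW 21.8, GRO 14.9 kg/day; breeds rarely
  kept purebred get mid-range values), a per-cow lognormal scale
  (sd 0.12), Wood shape b ~ N(0.20, 0.03), c ~ N(0.0030, 0.0004), and the
  scale a solved so the day-1–305 mean hits the target.
* **Noise**: stationary AR(1), sd 1.8 kg at the HOL yield level and
  scaled linearly with the cow's mean yield (the mean-variance coupling
  that motivates the aDMY covariate), ρ = 0.3.
* **Perturbations**: Poisson rate 1.5 per lactation, non-overlapping
  windows within days 11–340, duration 5 + (Geometric(0.12) − 1) capped at
  50 days, depth floor uniform on (0.55, 0.95) of the expected level,
  linear decline over a development phase (35 % of the duration) and an
  exponential return over the recovery phase — the profile stays strictly
  below 1 inside the episode, so truth boundaries are unambiguous.
* **Population**: herds of 50–300 cows; each herd draws a mean-HOL target
  from a configurable mixture and one alternative breed; non-HOL cows are
  HOL crossbreds with probability 0.5, otherwise purebreds of the
  alternative breed. Lactations run 305–340 days with 2 % missing days.

Ground truth records every injected episode, and `truth_feature_oracle`
computes the category-5 features the pipeline must reproduce in the
zero-noise limit, applying the same 85 %/70 % rules.

**The quartic-base option.** No quartic reproduces a Wood curve exactly,
and on noise-free data the τ = 0.7 fit rides systematically above ~70 % of
days (errors up to a few kg at the window edge), which creates spurious
or merged episodes. Exact zero-noise recovery checks therefore use
`base_curve="quartic"`, which replaces the base on days 11–340 with its
least-squares quartic approximation so the true curve is representable by
the expected-curve model; with it, detection reproduces every injected
episode's boundaries, class and loss exactly. The default base remains
the Wood curve.

**What the generator does not emulate**: seasonality and weather, pedigree
structure and genetic (co)variances, milking-robot session-level
artefacts, multi-parity carry-over, herd management trends over years, and
nested perturbations (episodes within episodes). Passing tests therefore
demonstrate correctness of the estimators on data satisfying the model's
assumptions, not robustness to every feature of real AMS data.

## Problem sizes in the test suite

Unit and property tests run on single lactations or populations of a few
hundred cows. The end-to-end power check simulates 20,000-cow populations
(the size at which halving one breed's perturbation rate is reliably
detectable at the Bonferroni threshold — at ~2,000 cows the same effect
sits around z ≈ −2.5 and is expected to miss) in 3 seeded replicates, and
requires a significant, correctly-signed PertNoTotal coefficient in at
least 90 % of them. The acceptance script repeats the same computation
with 2 replicates, plus the sampling, Cook's-distance, coverage and
recovery checks, all seeded from its `--seed` argument.

## Known limitations

* The expected-curve fit is exact for the pinball loss but the quartic
  family itself biases early-lactation fit (days 11–30) for steeply rising
  curves; features comparing Wood and expected geometry inherit that.
* Cook's removal is single-pass, not iterated; with heavy-tailed features
  a second pass would remove more points.
* The lag-1 autocorrelation over gapped series uses the full
  sum-of-squares denominator with a consecutive-pairs numerator; with many
  gaps it is biased toward 0.
* PertDeepest is an absolute deficit in kg; a relative variant would
  decouple it from yield level (the aDMY covariate compensates in the
  regressions).
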