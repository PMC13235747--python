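# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the `u5m` pipeline, stage by stage.

## Indicators and conventions

U5MR, IMR and NMR are probabilities of death before exact ages 5 years,
1 year and 28 days, expressed per 1000 live births.  Decimal years follow
the `year + fraction elapsed` convention (mid-year = x.5).  All
uncertainty intervals are 90% (5th-95th posterior percentiles), taken on
aggregated draws where aggregation is involved — never on summed
percentiles.  A year is 365.25 days and a week 1/52 year throughout.

## Data model and inclusion rules

Observations carry a value, a sampling standard error on the rate scale, a
reference year, and series/source metadata.  A series is all observations
derived from one survey, census, VR or sample-VR source.  Two inclusion
rules are built in: VR series need at least 80% population coverage
(boundary inclusive), and series carrying configured quality flags (e.g.
fieldwork disruption) are excluded.  Exclusions are flags with reason
strings, never deletions, so excluded series remain reportable; filtering
is idempotent.  Further rules are config-extensible rather than hard-coded.

## Trend model

The log true rate is a clamped cubic B-spline with equally spaced knots
(default spacing 2.5 years) and a second-order difference penalty on the
coefficients — values chosen to track the established penalized-spline
mortality literature; all are config-exposed.  The observation model is
log-normal with variance `se_i² (log scale) + σ²_{s(i)}`, plus a
source-type bias `b_s` in the mean.  Identification of the biases:

* when vital registration (meeting the coverage rule) is present it is the
  reference, with its bias fixed at zero;
* otherwise no source is anchored and every bias gets a mean-zero Normal
  prior (default sd 0.1 on the log scale).  The trend level is then only
  weakly identified, deliberately: the posterior median centres on the
  bias-shrunk average of the sources while the unresolvable bias
  uncertainty widens the interval, which is what calibrated coverage
  requires when no gold-standard source exists.

Priors: penalty precision τ ~ Gamma(1, 0.01); non-sampling sds σ_s ~
Half-Normal(0.15).  Sampling is a Gibbs sweep — joint conjugate Gaussian
update of (α, b), conjugate gamma update of τ, and log-scale
random-walk Metropolis for each σ_s — with 2 chains, 500 warmup and 500
retained draws per chain by default.  Convergence is monitored by
split-chain potential scale reduction on the log rate at five grid years;
fits exceeding 1.05 carry a warning flag in their metadata.  Non-sampling
variance is per source type, not per series — the smallest structure the
observation model needs.

IMR is fitted independently by the same machinery and capped per draw-year
at the matched U5MR draw (truncation, no swapping) to restore ordering.

### Extrapolation

From the last included data year to the common reference year (2024), each
draw declines at `0.5 × (its own ARR over the trailing 10 years) + 0.5 ×
(global ARR)`.  The global trend is the birth-weighted mean of country
posterior-median rates, and its ARR is taken over the same trailing
window; birth weighting is an explicit, swappable choice.  Extrapolated
years are flagged; countries with data in the reference year are returned
unchanged.

## Neonatal ratio model

The ratio `R = NMR/(U5MR − NMR)` is the product of an expected ratio and a
country multiplier.  The expected ratio is `log R = a + b·log U5MR` above
a low-mortality plateau (defaults a = 0.95, b = −0.31, plateau at U5MR 10
per 1000, calibrated so the implied NMR/U5MR share is ≈0.46 at U5MR 37
and ≈0.39 at U5MR 94); `fit_expected_ratio` recalibrates the curve from
any (U5MR, ratio) pairs.  The multiplier's log is a first-order random
walk centred at zero — the smallest model that lets deviations evolve over
time — with a Half-Normal(0.05) prior on the innovation sd and an
additional Half-Normal(0.1) observation-scale noise term; both take
Metropolis steps inside a Gibbs sweep whose state update is a conjugate
GMRF draw.  Observation errors enter by the delta method on the log
ratio.  Countries without neonatal data get a multiplier of exactly one.
No separate extrapolation is applied: late-year NMR inherits the
extrapolated U5MR through the expected ratio and the last multiplier
state.

## Adjustments

Trend fits use crisis-free data; deaths from qualifying crisis events are
added back post-fit as additive rates (deaths ÷ births × 1000) in the
event years, allocated across NMR/IMR/U5MR by the event's age pattern in
nested form so ordering is preserved.  Direct age-specific VR counts, when
an event carries them, override the pattern.  Which events qualify is a
data/config question (a `meets_criteria` flag on the event), not a
hard-coded rule.  HIV/AIDS adjustments use the same additive mechanics
from a per-year table of under-5 and neonatal additions; the infant
addition interpolates between them with a configurable share (default
0.75) because HIV child deaths concentrate in infancy.  Adjustments are
additive, order-independent across disjoint events, and invertible by
subtraction.

## Deaths engine

Annual birth cohorts are split into 52 equal weekly cohorts entering at
week midpoints `(k − 0.5)/52`.  Age is partitioned at 28/365.25 and 1 and
5 years; within a segment the hazard is constant
(`h = −ln(1−q)/Δt`), which makes the survival product reconstruct
`1 − U5MR/1000` exactly and lets each exposure interval integrate in
closed form.  Cohorts switch to the new calendar year's hazards at the
boundary instant.  Deaths accumulate into the calendar year of occurrence
by age group; computed per posterior draw, with births treated as fixed
(death-count intervals reflect rate uncertainty only).  Reported years
are complete from the fifth birth year onward (`complete_from`), since
earlier years lack the cohorts born before the series starts.

## Metrics

`ARR = ln(rate_t1/rate_t2)/(t2 − t1)`, positive for declines; uncertainty
from the per-draw ARR distribution.  Percent declines, the NMR/U5MR share
and death shares are simple ratios.  Reporting rounds ARRs to one decimal
(percent) and shares to two (ratio), matching standard presentation;
rounding happens only at the report layer.

## Projections

Projections operate on component rates — neonatal q(0-28d), conditional
post-neonatal q(28d-1y), conditional child q(1-5y) — so recombination
(`IMR = 1−(1−nmr)(1−pnmr)`, `U5MR = 1−(1−nmr)(1−pnmr)(1−cmr)`) keeps the
three indicators consistent by construction.  Component ARRs for 2015-24
come from the crisis-free posterior draws (median, or 5th/95th percentile
for the UI-bound variants); negative ARRs clamp to zero.  Floors (0.7,
0.1, 0.3 per 1000) are absorbing and never raise a country already below
them; the floors can also be recomputed from a synthetic world as the
lowest 2024 component values among countries with at least 10 000 births.
Target scenarios use log-linear paths from 2024 to the 2030 target.  When
both a U5MR and an NMR target bind, the NMR path is fixed first and the
post-neonatal and child components are scaled proportionally on the
log-survival scale so the recombined 2030 U5MR hits its target exactly —
a choice that preserves component consistency while honouring both
targets, and is isolated in one function if a different reconciliation is
wanted.  "On track" means the current-trends median 2030 value is at or
below the threshold, assessed on crisis-free projections.

## Synthetic data generator

The generator emulates the statistical structure the estimators assume:

* true log-U5MR follows a line whose slope (instantaneous ARR) performs a
  random walk (baseline U5MR log-normal around 90 per 1000, sd 0.6 on the
  log scale; mean ARR 3%/yr, between-country sd 1.2%, slope innovation
  0.004/yr) — a piecewise log-linear family matching what the spline
  fits;
* NMR comes from the expected-ratio curve times a country-level
  multiplier (log sd 0.15); IMR sits a fixed fraction (0.6) of the way
  from NMR to U5MR;
* series follow the usual quality hierarchy — VR least biased/noisy,
  summary birth histories most (log-scale bias sds 0 to 0.12, sampling
  sds 0.025 to 0.10) — with VR present in ~35% of countries, around three
  full-birth-history surveys each contributing retrospective estimates at
  5-year recall-window midpoints, and SBH series never reporting NMR;
* observations are drawn around the crisis-free truth
  (`obs = true × exp(bias + e)`); the reported standard error covers the
  sampling component only, leaving non-sampling error for the model to
  estimate;
* crisis spikes are additive on the rate scale (2% of country-years,
  log-normal size around 4 per 1000), recorded as events with an age
  pattern so the adjustment stage can reconstruct them;
* births grow exponentially (≈1%/yr) and are deterministic given the
  seed; everything is reproducible from a single seed via per-country,
  per-stream child generators.

The error-structure magnitudes are plausible placeholders spanning the
published data-quality hierarchy, not estimates of any real source.  The
generator does not emulate survey-specific designs, HIV-driven recall
bias, subnational structure, or correlated errors between series — so
passing tests show the estimators are correct and calibrated *under the
assumed error model*, not that real-world biases of different shapes
would be removed.

## Numerical choices and scale

Observation-variance floor 1e-8; a 1e-6 ridge on the spline block for
Cholesky stability; log-scale standard errors by the delta method
(`se/value`).  Tie-break for equal-rate inputs: zero conditional
probabilities give exactly zero hazards.  Degenerate inputs (no included
observations, empty worlds, all-excluded series) raise instructive errors
rather than producing silent output.  Test and reproduction problem sizes
— 100 synthetic countries with 2 chains × 1000 retained draws for the
recovery study, a 3-year toy for the daily-resolution cross-check, a
small synthetic world for scenario ordering — were chosen so the whole
suite runs in a couple of minutes on one CPU while keeping Monte-Carlo
error well inside the tolerances tested.

## Known limitations

* The production estimation system's survey-specific random effects,
  recall-bias submodels and HIV-period bias adjustments of birth-history
  inputs are out of scope.
* Regional intervals aggregate independent country draws; systems whose
  country posteriors are correlated would produce wider regional bands.
* Death-count uncertainty excludes live-birth uncertainty by design.
* The expected-ratio curve's default parameters are a calibration to
  headline global values, intended as defaults for synthetic work, not as
  re-estimates of the published global relation.
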