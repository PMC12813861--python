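# Methods

## Demand projection

The unit of demand is one ambulance transport record.  Records are
aggregated into age-gender strata on a configurable band scheme; the
default projection scheme is `0-64 / 65-74 / 75-84 / 85+`, while the
descriptive profile uses `<15 / 15-34 / 35-64 / 65+` (both schemes are
validated to be disjoint and gap-free, ending in an open band).
Records missing age or sex cannot be assigned to a stratum; they are
excluded from projection tables and the exclusion count is always
reported.  Triage level and trauma status are optional fields that feed
only the descriptive profile, never the projection.

The age-gender-adjusted projection multiplies each base-year stratum
demand by that stratum's population-change weight
`W = population(target)/population(base)` and sums.  Weights are kept
at full floating precision internally; two-decimal rounding is applied
only in reports.  The structure-blind ("unadjusted") projection scales
every stratum by the single overall both-sex all-age ratio — this is
the natural formalization of projecting demand from headline population
growth alone, and it is the comparison the misestimation percentage
`100·(unadjusted − adjusted)/adjusted` quantifies (negative values:
the blind projection underestimates).

Both-sex cells can be formed two ways, and the package exposes both:
`sum_of_sex` (male + female projections; the literal double sum, the
default) and `aggregate_weight` (both-sex weight × both-sex base
demand).  The two disagree exactly when male and female weights differ
within a band, which is pronounced in the oldest band of aging cities.
Source tables sometimes record both-sex base demand that exceeds
male + female because records with known age but missing sex are
counted there; `project_adjusted`/`project_unadjusted` accept an
optional `both_base` mapping for such independently recorded both-sex
totals.

Year-by-year trajectories recompute weights (including the overall
ratio) per year from that year's pyramid, so the unadjusted series uses
year-specific overall ratios.

## Base-year screening

Before adopting a base year, its yearly total is screened against
neighbouring years with a two-sided Grubbs (extreme studentized
deviate) test: `Z_i = |x_i − mean|/s` with the sample (n−1) standard
deviation, compared to `G = ((n−1)/√n)·√(t²/(n−2+t²))`,
`t = t_{α/(2n), n−2}`, at α = 0.05 by default (G ≈ 1.715 for n = 5).
A zero-variance sample yields all-zero Z and is never significant.

## Temperature model

Per stratum, daily counts are regressed on `(1, T, T²)` by OLS
(statsmodels), with t-based 95% confidence intervals (df = n − 3) and
adjusted R² = 1 − (1 − R²)(n − 1)/(n − 3).  All calendar days are used;
zero-demand days are genuine zeros, not missing.  The model order is
quadratic, matching the U-shaped cold/heat response; R² is expected to
be modest since temperature is one of many demand drivers, and its main
use is cross-stratum comparison.  A constant response has zero total
variance; the package reports adjusted R² = 0 in that degenerate case
rather than NaN.

Equation projection multiplies all three coefficients (and CI bounds)
by the stratum weight; goodness of fit is unchanged by rescaling, so
adjusted R² carries over.  Combined (summed) equations carry no CIs or
R².  Curve tables report raw predictions on a temperature grid —
negative values at extreme extrapolation are flagged, never clamped,
because the tables describe the fitted polynomial, not a forecast.

## Synthetic scenario generator

The generator emulates the three restricted inputs:

* **Population projection** — per-stratum exponential growth,
  `count(y) = round(base·(1+r)^(y−base))`.  Default base populations are
  Taipei-like 2015 values (about 2.78 M total; 85+ strata 21 k male,
  32 k female); default growth rates solve `(1+r)^36 = W(2051)` per stratum
  so the 36-year factors match the published 2051 weights (the largest:
  women 85+, factor 10.13).  Exponential interpolation makes the
  intermediate-year factors smooth; they need not match any published
  intermediate column exactly.
* **Temperature** — `T(d) = mean + amplitude·cos(2π(doy−phase)/365.25)
  + N(0, sd)`, default mean 23 °C, amplitude 6 °C, peak at day 197
  (mid-July) and daily noise sd 2 °C, a plausible subtropical urban
  year.
* **Records** — per stratum-day Poisson counts with rate
  `max(0, c0 + c1·T + c2·T²)` scaled by the stratum's population
  relative to the base year, expanded to records with uniform ages
  within the band (open band sampled on 85–100), and triage/trauma
  drawn from the published 2015 frequency profile (2% of triage values
  are dropped to exercise missing-data paths).

Default rate curves take their shapes from the published base-year
regressions and are each rescaled by a single multiplicative factor so
the deterministic-climate yearly expectation equals the published 2015
stratum total.  This calibration is needed because two-decimal printed
coefficients alone misstate some yearly totals by ±15%.  The Poisson
count law is a modelling choice (the analysis itself fits plain OLS);
`ground_truth` returns the exact weights (ratios of the generated,
integer-rounded pyramids), the rate coefficients and closed-form yearly
expectations, including the Jensen correction `b2·sd²` per day for
temperature noise (exact while the rate stays positive).

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: overdispersion and serial
correlation of daily counts, day-of-week and holiday effects, records
missing age or sex, spatial structure, and non-temperature drivers of
demand.  One visible consequence: with Poisson noise, the cross-stratum
ordering of adjusted R² follows each curve's signal-to-noise ratio, and
the female 65–74 stratum — not the oldest band, as in observed city
data — attains the largest value; the suite therefore checks that the
fitted adj-R² maximum coincides with the ground-truth signal-to-noise
maximum rather than asserting the observed-data ordering.

## Numerical and design choices

* Dates are ISO-8601; leap days kept; daily table keys are calendar
  dates spanning the full record range.
* All randomness flows through `numpy.random.default_rng` seeded from
  `(seed, year, stream)`; identical config + seed gives byte-identical
  output files.
* Report rounding is centralized: weights 2 dp, equation coefficients
  2 dp, demand integers, misestimation integer percent.  Full precision
  everywhere upstream.
* Every output CSV carries a header comment with package version,
  config hash (input paths and analysis settings; output directory
  excluded) and seed.
* Pipeline test and demonstration runs use rate curves scaled to ~10%
  of the Taipei volume (~13 k records/year), which leaves all ratios,
  weights and curve shapes unchanged.
* The open-ended age band is uncapped for binning; only synthetic age
  sampling caps it (default 100).

## Known limitations

* Pyramids are inputs: no cohort-component projection
  (fertility/mortality/migration) is performed.
* Point projections only; no uncertainty intervals are attached to the
  demographic projection (the weights are treated as given).
* The temperature model has no lags, humidity or heat-index
  covariates, and no count-GLM alternative; OLS CIs on count data are
  approximate (measured coverage on Poisson simulations is close to
  nominal at typical daily rates).
* Misestimation percentages are undefined for strata with zero
  adjusted demand.
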