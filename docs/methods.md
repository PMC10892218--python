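# Methods

## Study design being modelled

The package implements a retrospective drug-utilization design on
reimbursed-dispensation claims: a cohort of young adults (18–22 years at
their index date, the first in-period fill) with at least one antidepressant
dispensation (ATC N06A) over a 200-week index period (1 January 2018 –
1 November 2021), interrupted on 9 March 2020 (start of the first Italian
lockdown). Week *k* covers the half-open day span
[start + 7(k−1), start + 7k) and is labelled by its end date start + 7k;
weeks 1–114 form the pre-interruption segment and weeks 115–200 the
pandemic segment. Two printed week/date anchors in the source material are
inconsistent with the convention fitted by all others; the convention is
kept and the outliers are not forced to agree.

## Treatment episodes

Days of supply of a dispensation = (packages × units/package × mg/unit) /
DDD, with WHO DDDs for the 14 study drugs held in a registry table.
Scanning a subject's fills in date order within a drug group (a single ATC,
an ATC class, or the N06A umbrella), fill *i+1* continues the current
episode iff its gap from fill *i* is at most `grace_factor` × supply*i*
(default 1.5, anchored at the fill date; an exhaustion-anchored variant is
config-selectable). Same-day fills pool their supplies. An episode ends one
(ceil-rounded) supply after its last fill, clipped at the start of a
successor so episodes stay disjoint even for grace factors below 1. The
implementation is validated against an independent day-by-day stock
simulation on randomized histories (1,000 in the acceptance suite, plus a
property-based test), and satisfies monotonicity (more grace, fewer
episodes) and conservation bounds.

Fills up to 12 weeks before the index period are accepted so that episodes
already running at the period start are seeded; correspondingly the first
12 index weeks ("burn-in") are excluded from model fitting downstream,
because their episode ascertainment is left-truncated.

## Prevalence estimation

Overall prevalence = distinct users / reference population, where the
denominator is by default the rounded mean of the yearly 1-January counts
over the four calendar years (first-year rule selectable). Weekly
prevalence uses as denominator the population of the year containing the
week's first day. All intervals are exact central binomial
(Clopper–Pearson, beta-quantile form); rates are reported per 10,000 with
half-up rounding to one decimal. Sex strata use sex-specific denominators
when the population table provides them, otherwise the total population
(the series is then flagged `denominator_is_total`). Sex contrasts are
odds ratios with Wald log-scale intervals, the Haldane–Anscombe 0.5
correction when a cell is zero (flagged), and two-sided Fisher exact
p-values in the probability-mass convention.

## ARIMA counterfactual

The pre-interruption rates (weeks 13–114, n = 102) are fitted by a
stepwise AICc search in the spirit of the Hyndman–Khandakar algorithm:
KPSS tests choose the differencing order d (max 2); starting orders
(2,2), (0,0), (1,0), (0,1) are refined by ±1 neighbour moves in p and q
(bounds 5/5) and in the seasonal orders. Seasonal terms (period s = 52)
are considered only when the series holds at least two full cycles plus a
margin; the 102-week default series does not, so the search collapses to
the non-seasonal family — the standard auto-ARIMA behaviour for short
series. Fitting is by state-space maximum likelihood (statsmodels SARIMAX)
with no stochastic restarts, so selection is deterministic given the data.
Candidates whose AR or MA roots lie on the unit circle are rejected (they
signal boundary overfits with degenerate forecast variances).

Three deliberate choices depart from a naive auto-fit, each motivated by
the counterfactual use of the model rather than one-step forecasting:

* **Deterministic component tied to d.** d = 0 keeps a constant plus
  linear trend, d = 1 keeps a drift, d = 2 none. For a visibly trending
  series, AICc often drops a weak drift term; the resulting flat forecast
  is indefensible as an 86-week counterfactual, so the trend component is
  treated as structural and not searched over.
* **Variance stabilization (default `sqrt`).** The weekly numerator is a
  count whose innovation variance scales with its level, and the level
  roughly triples over the study window; a single innovation variance
  fitted on the raw scale therefore understates post-period uncertainty.
  Rates are fitted on the square-root scale by default (`none` and `log`
  selectable); forecasts and interval bounds are mapped back through the
  monotone inverse (the back-transformed centre is a median forecast).
* **Trend-coefficient uncertainty in the intervals.** State-space
  prediction intervals condition on the estimated parameters, but the
  error of an estimated drift grows linearly in the horizon and dominates
  long-horizon uncertainty; its first-order contribution (h·se)² is added
  in quadrature.

The fitted model is frozen and forecast over the whole pandemic segment
(no re-fitting after the interruption), with normal-theory 95% prediction
intervals, clipped below at zero for reporting. Comparison reconstructs
per-week user counts from rates (half-up rounding against the weekly
denominator) and forms observed-vs-predicted 2×2 tables, reporting
per-week differences per 10,000, odds ratios with Wald intervals, the week
of maximum |difference| and the first week from which the observed rate
exceeds the prediction persistently.

## Synthetic registry

The generator emulates the administrative claims stream the analysis
expects, not any particular patient-level mechanism:

* **Initiations**: a time-inhomogeneous weekly Poisson process with
  intensity λ(k) = (λ₀ + slope·k) · effect(k). A 520-week warm-up before
  the recording window (10 years, beyond the duration distribution's
  practical support) opens the registry with a stationary stock of
  prevalent users whose earlier fills are simply not recorded — exactly
  the left-truncation the burn-in weeks compensate for. With a linear
  intensity and stationary warm-up the expected active-user path is linear
  in the null case, rising from ≈6 to ≈30 active users over the
  pre-period.
* **Persistence**: per-class episode durations are log-normal, median
  150 days, σ = 0.6 (mean ≈ 180 days ≈ 26 weeks), the scale real-world
  antidepressant persistence studies report. Shorter medians make the
  joint calibration targets infeasible (a sustained +25/10,000 excess
  would require more initiators than the total user budget); much longer
  medians give the weekly series long-memory level wander that no
  low-order ARIMA interval can honestly cover.
* **Dispensing**: one fill covers at least the 28-day target cadence
  (packages per fill = ceil(28 / single-pack supply)); refills occur at
  supply exhaustion with Gaussian date jitter (sd 1.5 d).
* **Demographics and drug mix**: P(female) = 0.603; drug-class sets drawn
  from an explicit 7-subset distribution hitting the class shares 73.1% /
  21.8% / 16.6% and a 12.2% multi-class share (the four printed shares are
  arithmetically inconsistent by 0.007 probability mass, resolved by
  renormalising with zero triple-class mass); one drug per class with
  within-class weights making sertraline the most and clomipramine the
  least dispensed drug; ages uniform in [18.05, 22.6] years at the (first
  in-period) index date.
* **Interruption**: effect(k) multiplies initiations — 1 before week 115,
  a dip multiplier 0.25 over weeks 115–133, then a linear ramp from week
  134 reaching a rise multiplier at week 170, held to the end. A config
  switch moves the rise onto episode durations (reduced discontinuation)
  instead.

Calibration is analytic, not trial-and-error: expected active counts are
convolutions of the intensity with the log-normal survival, expected user
counts sum the intensity with a survival-weighted appearance probability
for warm-up cohorts, and the excess at week 170 is affine in
(rise − 1), so the rise multiplier solves in closed form and λ₀/slope
rescale by fixed-point iteration (`calibrate_to_targets`). The shipped
defaults are that calibration's output: ≈1071 expected users and an
expected +25/10,000 excess at week 170. Because total users are pinned
while the sustained excess persists ≈9 months, roughly 60% of all users
arrive through the interruption effect — a large relative rise (multiplier
≈10 on a small base) that is forced by the joint targets.

A truth record accompanies every registry: realized weekly active users
(per class and umbrella, from per-fill coverage), the effect path, and
cohort tallies. With jitter disabled, the episode pipeline reproduces the
per-class truth counts exactly; at the umbrella level exact equality is
unattainable by construction (the episode end rule uses the last fill's
own supply, which can undercut a longer co-dispensed supply), so the
default-jitter comparison is held to ≤2% mean absolute relative error.

**What the generator does not emulate**: dose changes, switching,
stockpiling behaviour, seasonality, demographic turnover, regional
population drift, or the week-by-week values of the real registry. In
particular, the printed weekly odds ratios of the source study imply a
weekly prevalence baseline (~100–120 per 10,000) that is not reconcilable
with 1071 distinct users unless essentially all users are continuously
treated; the generator honours the countable targets and lets the weekly
baseline fall where realistic persistence puts it (~3–5 per 10,000).
Passing tests therefore validate the pipeline's statistical machinery
under the stated study conditions, not the real registry's trajectories.

## Numerical conventions and degenerate inputs

ISO-8601 dates, UTF-8 CSV throughout; half-up decimal rounding for printed
rates; episode ends ceil partial supply days; zero-cell 2×2 tables get the
0.5 correction and a flag; x = 0 / x = n binomial bounds are exact 0 / 1;
empty drug groups are skipped in the pipeline with a warning rather than
failing the run; a series whose interruption falls at its end yields an
empty post segment and a warning. Seeds: a single integer drives the whole
registry (NumPy default generator); identical configs are byte-identical.

## Problem sizes in the test suite

Unit oracles run at n ≤ 20 fills; the acceptance suite uses 1,000 random
episode histories, 2,000 binomial draws for interval coverage, and 50
seeds × (null + effect) full pipeline runs (simulate → episodes →
prevalence → ITS) for counterfactual validity, chosen to keep the full
suite around two minutes on one CPU while leaving the Monte-Carlo bands
(coverage ≥ 90%, median recovered excess within ±30%) well resolved.

## Known limitations

* The stepwise search explores a neighbourhood, not the full order grid;
  like all auto-ARIMA procedures it can settle on a local AICc optimum.
* Prediction intervals account for innovation variance and trend-slope
  error but not full parameter covariance or model-selection uncertainty.
* The OR-vs-predicted comparison treats the forecast as a fixed
  denominator count; no formal test is attached to it, matching the
  descriptive use of the counterfactual.
* DDD-based supply assumes maintenance dosing; actual prescribed doses are
  invisible in claims.
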