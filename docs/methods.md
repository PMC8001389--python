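# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the limitations of `ovitherm`.

## Data model

The unit of laboratory observation is the egg cluster (10–15 eggs laid
within 24 h), censused daily: eggs alive by colour stage (yellow → brown →
head-capsule visible / black), plus cumulative hatched and dead counts.
Events are dated to the day of first detection, so all event ages are
integers in days; sub-day timing is unobservable under a daily protocol.
`derive_fates` converts cluster tables to per-egg records by differencing
the cumulative counts; eggs alive at the end of observation are censored
there. The study that motivated the design ran all eggs to completion, so
censoring is an extension needed only for horizon-truncated synthetic runs.

Per-egg colour-stage durations are generally under-determined by
cluster-level colour counts. They are reconstructed only in the lockstep
case (every census has all live eggs in a single colour and all hatches
fall on one day); otherwise they come from per-egg long-format input (the
generator's ground truth) or are absent. Analyses that need stage durations
report "not available" (an empty table) rather than guessing.

## Survival analysis

*lx*, the probability at laying of being alive at age *x*, is estimated by
the Kaplan–Meier product-limit method per temperature × RH group. Death in
the egg is the event; hatching is right-censoring, because a hatching larva
leaves the egg stage alive. The risk set at age *t* includes every egg
whose event age is ≥ *t* (deaths before censorings at ties). Groups are
compared with the standard k-sample log-rank statistic: at each distinct
death age the observed deaths per group are compared with their
hypergeometric expectation given the margins; the quadratic form
U′V⁻U over the first k−1 groups (Moore–Penrose generalized inverse, the
standard identifiability handling) is referred to χ² with k−1 df. Pairwise
regime comparisons within each temperature report raw per-pair p-values
with df = 1 and no multiplicity adjustment, matching how such tables are
conventionally reported.

Eggs are treated as independent subjects; within-cluster correlation is
ignored. This matches the degrees of freedom conventionally reported for
this design but will anti-conservatively narrow p-values if cluster
frailty is material — a known limitation, out of scope here.

## Development time

Only eggs that completed development enter duration analyses. Hatch age
(integer days) is modelled as Poisson with a log link — the convention in
incubation studies even though durations are not true counts. The Pearson
dispersion (χ²/df) is reported so overdispersion (or, for durations with
CV ≪ 1, underdispersion) is visible; no quasi-likelihood correction is
applied, keeping the stated model. Per-term χ² values use Type-II analysis
of deviance — each term is dropped from the model containing every other
term that does not include it — which is the standard choice for
unbalanced factorials and is invariant to factor-level relabelling.

Post-hoc comparisons use Tukey's HSD on the linear-predictor scale:
level means are estimated marginal means (design rows averaged over the
observed levels of the other factors), pairwise differences are compared
with studentized-range critical values at the model's residual df, and the
compact letter display is built greedily from the sorted means (maximal
runs of mutually non-significant levels share a letter). α defaults to
0.05. Pairing an HSD routine with a Poisson GLM requires choosing a scale;
the linear-predictor (log) scale is the defensible analogue because that is
where the model is additive.

## Linear rate model

The development rate per condition is the reciprocal of the mean duration
(not the mean of per-egg reciprocals — conventional in degree-day studies,
and less biased at moderate CV). Unweighted ordinary least squares of rate
on temperature is fitted per RH regime. By default every point warmer than
the empirical rate maximum is excluded (the 36 °C point under the reference
design, where the rate has turned over and R² near 0.99 would otherwise be
unattainable); a flag allows inclusion. The fit reports F (= t² of the
slope in simple regression), p and R², and derives

* lower development threshold T0 = −a/b (°C),
* thermal constant K = 1/b (degree-days),

identities applied exactly (to machine precision). A fit with non-positive
slope is flagged invalid with T0/K unset. `regression_from_coefficients`
applies the same derivation to externally supplied (published) coefficient
pairs. Note that coefficients printed to 2 significant figures propagate
~1% uncertainty into T0 and K; derived values should be compared within
that rounding tolerance.

## Degree-day phenology

Thermal accumulation uses the temperature-mean method: daily
DD = max(0, Tmean − T0), no upper cutoff. Weekly climatologies are built by
binning days into 52 calendar weeks (day-of-year blocks of 7, the last week
absorbing the remainder), averaging across the configured number of years,
and expanding back to constant-within-week daily values. Forecasting finds
the first day on which the accumulation since laying reaches K. By default
the day of laying itself does not contribute (accumulation starts the next
day), so at constant temperature the hatch lag is exactly
⌈K/(T − T0)⌉ days; `include_lay_date=True` switches to the other
convention. Hatch dates are monotone in lay date on any fixed series.

The oviposition window is back-calculated from field stage records using
reference stage durations at 8 °C (the winter mean temperature in the
target region; configuration inputs, default 15 + 23 + 12 = 50 days
matching the medium-regime linear law at 8 °C and the default stage
fractions). The start is the earlier of (first larva date − total egg
duration − larval age at detection, default 0) and (first head-capsule-egg
date − yellow − brown durations), clipped to be no earlier than the first
reproductive-adult capture when adult records exist. The end is the date of
the last yellow-cluster record; its lay date lies within the preceding
yellow-stage duration, and that uncertainty interval is attached to the
returned evidence. When no yellow record exists but older egg stages do,
the end falls back to the latest-possible lay bound of the oldest stage
present; the window is undeterminable only when larvae, head-capsule eggs
and yellow clusters are all absent.

## Synthetic-data generator

The generator emulates the reference factorial design: 8 temperatures
(8–36 °C in 4 °C steps) × 3 RH regimes, 20 clusters per condition, cluster
sizes uniform on [10, 15].

* **Fate.** Each egg hatches with the per-condition probability of the
  survival surface, else dies. The default surface is an explicit
  per-condition table calibrated once to the ordinal patterns reported for
  this system — medium RH best at the thermal extremes (8 and 36 °C, all
  three regimes distinct), high RH best at 12–20 °C (medium ≈ low), low RH
  clearly worst at 24–32 °C (medium ≈ high), and a steep decline above
  28 °C with roughly half the eggs surviving low RH at 8 °C. A single
  parametric curve with additive regime offsets cannot produce a regime
  ranking that changes non-monotonically across temperature, hence the
  tabular default. No per-cell percentages were available to anchor to, so
  the defaults are calibrated to ordinal structure only.
* **Duration.** Hatched eggs draw a discretised gamma duration (shape
  1/CV², minimum 1 day) with mean K/(T − T0) from per-regime truths
  (defaults: T0 = 3.82/3.40/3.30 °C and K = 209.05/230.83/246.14 DD for
  high/medium/low), times a supraoptimal inflation factor (default 1.35)
  above the optimum (default 32 °C) — a deliberate stand-in for a full
  nonlinear rate curve, which is out of scope. The default CV of 0.1
  reflects daily-resolution recording of durations spanning 8–50 days.
* **Death timing.** Uniform on [1, would-be duration]: a maximum-entropy
  placeholder, documented and swappable, since no death-timing distribution
  was available to calibrate against.
* **Colour stages.** Each duration is partitioned by stage fractions
  (default 0.30/0.45/0.25, brown longest) with largest-remainder rounding.
* **Tables.** Daily cluster tables are the exact tally of the per-egg
  ground truth, so they pass every validator and reconcile with
  `derive_fates` by construction.

Temperature series are a sinusoidal annual cycle (default mean 15 °C,
amplitude 9.5 °C, coldest mid-January — an inland Ebro-Valley-like
Mediterranean climate) plus AR(1) noise (stationary SD 2 °C, lag-one
correlation 0.7). Field records place a fixed number of egg clusters on
every day of a known oviposition window and age them deterministically
through the reference stage durations; sampling dates then report the
stages present, with reproductive-adult records on window sampling dates.

What the generator does **not** emulate: within-cluster correlation of
fates, observation error in the daily censuses, nonlinear rate curvature
below the optimum, between-area climatic differences beyond independent
noise, and non-uniform laying intensity over the window. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to those real-data features.

## Numerical choices

* Log-rank covariance inversion: Moore–Penrose pseudo-inverse on the
  (k−1)×(k−1) block; a degenerate (zero) variance yields χ² = 0.
* GLM fitting: IRLS to deviance tolerance 1e-8, 100-iteration cap,
  non-convergence raised as an error.
* OLS: `scipy.stats.linregress`; T0/K identities exact given the slope.
* Largest-remainder rounding breaks ties by the largest fractional part,
  stable in stage order.
* Problem sizes in the test suite mirror the study design (20 clusters ×
  10–15 eggs × 24 conditions) for calibration checks, with reduced designs
  (3 clusters × 4–6 eggs) for structural checks where only counts and
  degrees of freedom matter; null calibration of the log-rank test uses
  5,000 two-group simulations of 100 subjects each.

## Known limitations

* Cluster-level correlation is ignored throughout (egg-level analysis).
* The Poisson duration model tolerates rather than corrects dispersion.
* The linear rate model is only valid below the optimum; no
  Briere/Lactin/Logan-type nonlinear models and no upper-threshold or
  sine-wave degree-day methods are provided.
* The first-larva back-calculation assumes detection at hatching
  (larval age 0) unless a larval age is supplied.
* Published coefficients rounded to 2 significant figures limit the
  precision of any T0/K derived from them to about 1%.
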