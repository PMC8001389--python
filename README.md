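# ovitherm

Thermal biology of insect egg cohorts: survival under temperature ×
relative-humidity stress, linear development-rate modelling, degree-day
phenology and oviposition-window estimation.

`ovitherm` is aimed at pest-phenology researchers and IPM practitioners who
rear egg cohorts at constant temperatures and need to go from daily census
tables to field-level forecasts. It was built around the egg biology of the
alfalfa weevil (*Hypera postica*), whose females lay through autumn and
winter, but every stage is parameterised and works for any insect whose egg
development is adequately described by a lower threshold and a thermal
constant.

## What it computes

**Survival.** Each egg's fate (hatched, died, censored) is resolved from
daily cluster censuses. The age-specific survival rate
*lx* — the probability at laying of still being alive at age *x* — is
estimated per temperature × RH condition with the Kaplan–Meier
product-limit estimator (death is the event; hatching leaves the egg stage
alive and is censoring). Curves are compared with k-sample and pairwise
log-rank tests.

**Development time.** Hatch ages of eggs that completed development are
modelled with a Poisson GLM (log link) in temperature, RH regime, colour
stage and their interactions, with Type-II analysis-of-deviance χ² per term
and Tukey-HSD compact letter displays for post-hoc comparisons.

**Rate model.** Per condition, the development rate is the reciprocal of
the mean duration, *r*(T) = 1/D(T). Within the suboptimal range the rate is
linear in temperature,

    r(T) = a + b·T,   T0 = −a/b,   K = 1/b,

where T0 (°C) is the lower development threshold and K (degree-days) the
thermal constant. Supraoptimal temperatures (where the rate has already
turned over, 36 °C in the reference design) are excluded from the fit by
default.

**Phenology.** Daily thermal accumulation uses the temperature-mean method,
DD = max(0, Tmean − T0), with no upper cutoff; an egg laid on day *d*
hatches on the first day the accumulation since *d* reaches K. The
oviposition window is back-calculated from winter field records: the first
larva (or first head-capsule egg) bounds the start, validated against the
first reproductive-adult capture in autumn; the last yellow-cluster record
bounds the end.

**Synthetic data.** Because cohort experiments are laborious, the package
ships a generator that emulates the full factorial design — 8 temperatures
(8–36 °C) × 3 RH regimes (high 90–100%, medium 50–75%, low 10–35%), 20
clusters of 10–15 eggs each — with known ground truth, so every stage of
the pipeline can be validated end to end.

## Worked example

```python
from ovitherm import synthetic, devtime, thermal, survival

params = synthetic.GeneratorParams(seed=42)
observations, fates = synthetic.generate_experiment(params=params)

overall = survival.logrank_test(fates, group_by="condition")
print(f"overall log-rank: chi2={overall.chi2:.1f}, df={overall.df}, p={overall.p:.3g}")

summary = devtime.summarize_development(fates)
points = thermal.development_rates(summary)
for regime, fit in thermal.fit_rate_models(points).items():
    print(f"{regime:>6}: b={fit.slope_b:.4f}  a={fit.intercept_a:.4f}  "
          f"R2={fit.R2:.4f}  T0={fit.T0:.2f} degC  K={fit.K:.1f} DD")
```

prints

```
overall log-rank: chi2=3739.7, df=23, p=0
  high: b=0.0048  a=-0.0178  R2=0.9993  T0=3.74 degC  K=210.2 DD
   low: b=0.0041  a=-0.0137  R2=0.9996  T0=3.35 degC  K=244.1 DD
medium: b=0.0043  a=-0.0142  R2=0.9997  T0=3.33 degC  K=233.8 DD
```

The 24 survival curves differ strongly (χ² = 3739.7 on 23 df), and the
per-regime linear fits recover the generator's true thresholds (3.82, 3.40
and 3.30 °C) and thermal constants (209.1, 230.8 and 246.1 DD) to within a
few percent at the study's sample size.

The same pipeline runs from the shell against CSV inputs:

```sh
ovitherm --seed 42 --out-dir runs/demo run-all
```

which writes `cohort.csv`, survival-curve and log-rank tables, the
analysis-of-deviance and letter-display tables, a per-regime `thermal_fit.csv`
(b, a, F, p, R², T0, K), weekly hatch forecasts per area and the estimated
oviposition window per area, plus a manifest recording seed and config hash.

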