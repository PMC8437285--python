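# mrcea — mendelian-randomisation cost-effectiveness analysis

`mrcea` estimates the long-term causal effect of body-mass index (BMI)
on two health-economic outcomes — mean quality-adjusted life years
(QALYs) per year and mean healthcare cost (GBP) per year — using a
polygenic risk score as an instrumental variable, and turns those
dose–response estimates into net-monetary-benefit (NMB) evaluations of
BMI-lowering interventions such as bariatric surgery or restrictions on
promotions of high-fat/salt/sugar (HFSS) foods.

It is written for epidemiologists and health economists who want
causal, confounding-robust inputs to cost-effectiveness models instead
of observational regression coefficients, and for methodologists who
want a fully synthetic, ground-truth-known test bed for this style of
analysis.  Real biobank data of this kind is access-controlled, so the
package ships a seeded synthetic-cohort generator with the same
statistical structure (Hardy–Weinberg genotypes, an instrumented
exposure, a latent confounder, condition/cost event ledgers, heavy
primary-care missingness); every stage of the pipeline is tested
against it.

## The model

With genotype dosages `G`, a polygenic score `Z = Σ_j w_j G_j`
instruments BMI `X`.  For outcome `Y` (QALYs/year or cost/year) and
covariates `C` (age, sex, recruitment centre, 40 genetic principal
components), the additive structural mean model is estimated by
two-stage least squares,

    X = π Z + Cγ₁ + v        (first stage)
    Y = β X̂ + Cγ₂ + ε        (second stage)

with heteroskedasticity-robust (HC1) standard errors; `β` is the mean
change in the outcome per +1 kg/m². QALY effects are reported ×100 as
percentages of a QALY.  Around the main estimate the package provides:

- **Diagnostics** — robust first-stage F (weak instruments), Hausman
  endogeneity tests (2SLS vs the OLS comparator).
- **Summary-statistic sensitivity estimators** over per-SNP effects:
  IVW, MR-Egger (directional pleiotropy via its intercept), weighted
  median, simple and weighted mode, Cochran's Q.
- **Nonlinear MR** — localised average causal effects (LACE) within
  quantiles of *PRS-free BMI* (the residual of BMI on instrument and
  covariates), age-band and WHO-category stratification, and a
  variance-weighted cubic dose–response curve `β(b)`.
- **Multiple imputation** — predictive-mean-matching chained equations
  for the ~69% of the cohort missing primary-care outcomes, pooled by
  Rubin's rules.
- **Policy engine** — maps an intervention to per-person ΔBMI,
  integrates `∫ β(b) db` over the traversed BMI range per stratum,
  discounts multi-year streams (3.5%/year), and reports
  `NMB = λ·ΔQALY − ΔCost − intervention cost` at λ = £20,000/QALY with
  Monte-Carlo uncertainty intervals, aggregated over a population
  age × BMI distribution.

## Worked example

```python
from mrcea import GeneratorConfig, generate_cohort, two_stage_least_squares, ols_comparator
from mrcea.mr import RegressionSpec
from mrcea.nonlinear import quantile_lace, fit_dose_response
from mrcea.policy import (bariatric_surgery, EconomicConfig,
                          synthetic_population_england_wales, run_policy)

cohort = generate_cohort(GeneratorConfig(n_individuals=20_000, seed=1))
data = cohort.analysis_table()

spec = RegressionSpec(outcome="qalys_per_year")
iv = two_stage_least_squares(data, spec)
ols = ols_comparator(data, spec)
cost = two_stage_least_squares(data, spec.with_outcome("total_cost_per_year"))
print(f"2SLS : {iv.beta_pct:+.2f}% of a QALY per kg/m^2 "
      f"(95% CI {iv.ci95[0]*100:+.2f} to {iv.ci95[1]*100:+.2f}), first-stage F = {iv.first_stage_F:.0f}")
print(f"OLS  : {ols.beta_pct:+.2f}% of a QALY per kg/m^2")
print(f"2SLS : {cost.beta:+.2f} GBP/year per kg/m^2 (95% CI {cost.ci95[0]:+.2f} to {cost.ci95[1]:+.2f})")

curves = {}
for key, out in (("qaly", "qalys_per_year"), ("cost", "total_cost_per_year")):
    strata = quantile_lace(data, spec.with_outcome(out), n_quantiles=10, min_stratum=500)
    curves[key] = fit_dose_response(strata)

pop = synthetic_population_england_wales(2017)
res = run_policy(bariatric_surgery(), curves, pop, EconomicConfig())
print(f"bariatric surgery (BMI >= 35, 20 years): dQALY {res.delta_qaly_per_person:+.2f}, "
      f"dCost {res.delta_cost_per_person:+,.0f} GBP, NMB {res.nmb_per_person:+,.0f} GBP per person")
```

prints (exact output of this script on this seed):

```
2SLS : -0.62% of a QALY per kg/m^2 (95% CI -0.95 to -0.29), first-stage F = 348
OLS  : -0.77% of a QALY per kg/m^2
2SLS : +45.63 GBP/year per kg/m^2 (95% CI +31.99 to +59.27)
bariatric surgery (BMI >= 35, 20 years): dQALY +0.86, dCost -8,489 GBP, NMB +16,173 GBP per person
```

Reading the numbers: each extra kg/m² of BMI causes a loss of ~0.6% of
a QALY per year and ~£46/year of extra healthcare costs in this
synthetic cohort (whose generating truth is −0.65% and +£42.23); the
OLS estimate is pulled away from the truth by the built-in confounder
while 2SLS is not; F ≈ 348 rules out weak-instrument bias at this
sample size.  Feeding the fitted dose–response into the policy engine,
a 25% BMI reduction for everyone at BMI ≥ 35, held for 20 years and
discounted at 3.5%/year, buys ~0.86 QALYs and saves ~£8,500 per
person, for a positive NMB after the £9,549 procedure cost — i.e. the
intervention is cost-effective at £20,000/QALY.

A full end-to-end run (simulation → outcome construction → MR →
sensitivity → nonlinear → imputation → policy, with a per-run manifest)
is also available from the shell:

```bash
mrcea all --seed 3 -n 5000 --out demo_run
```

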