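# Methods

This note documents the models, conventions and design choices behind
`mrcea`, in the order the pipeline runs them.

## Synthetic cohort generator (`mrcea.synth`)

The generator exists because individual-level biobank data with linked
primary/secondary-care records is access-controlled.  It reproduces the
*statistical structure* the analysis relies on, with a known generating
truth, so that estimator properties (coverage, bias directions,
breakdown behaviour) can be demonstrated rather than asserted.

**Genotypes.** `m = 69` independent SNPs, dosages
`G_j ~ Binomial(2, f_j)` (Hardy–Weinberg), allele frequencies drawn
once, deterministically, from U(0.1, 0.9).  Linkage disequilibrium,
family structure and population stratification are deliberately not
modelled (the 40 "principal components" are pure noise covariates);
passing tests therefore say nothing about robustness to those
features of real data.

**Instrument strength.** Per-allele effect magnitudes follow a
long-tailed |N(0.03, 0.12)| — many small hits, a few large ones, as in
GWAS results for adiposity — rescaled so the score explains
`prs_r2 = 1.64%` of BMI variance.  That value makes the expected
first-stage F ≈ n·R²/(1−R²) match the published scale (≈5,200 at the
full-biobank n of ~311k), scaling proportionally at reduced n (≈340 at
the n = 20,000 used throughout the tests).  The dispersion of
per-SNP effects matters in its own right: the Egger/median/mode panel
is only informative when instrument strengths genuinely vary more than
their estimation error.

**Exposure.** `BMI = 27.4 + (G·w − mean) + κ_U·U + e`, with `U` a
standard-normal latent confounder (default κ_U = 1 kg/m² per SD) and
residual noise sized so the marginal SD is 4.8 kg/m².

**Outcomes — two channels.**

* The *annual channel* emits QALYs/year and costs/year directly from
  the structural model: a (possibly BMI-dependent) true effect
  integrated from the reference BMI of 27.4, confounder and age terms,
  optional per-SNP direct ("pleiotropic") effects, Gaussian QALY noise
  (SD 0.15) and right-skewed centred-gamma cost noise (SD ≈ £600,
  matching the strong positive skew of real cost data).  Replicate-
  heavy simulation studies use this channel; it is also the only one
  supporting pleiotropy and nonlinear truths.
* The *ledger channel* emits what a real pipeline ingests: dated
  condition onsets, prescriptions, appointments, inpatient episodes
  and deaths.  Condition k onsets with constant hazard
  `h_k·exp(κ·s_k·(BMI−ref) + c_u·U)`; deaths with hazard
  `λ·exp(γ_d·(BMI−ref))`; healthcare-use rates are mean-normalised
  log-linear in BMI (and in the confounder, routed through the
  high-value inpatient channel), with a multiplicative loading on the
  active-condition count for prescriptions.

**Calibration.** Default true effects are −0.0065 QALYs and
+£42.23 per kg/m²-year.  For the ledger channel these are hit
analytically rather than by numeric search: with constant hazards the
expected fraction of a T-year follow-up spent with a condition is
`f(h) = 1 − (1−e^{−hT})/(hT)`, so the QALY slope contributed by
condition k is `−d_k·f′(h_k)·h_k·κ·s_k` and κ solves a linear
equation (after subtracting the mortality contribution, obtained from
the alive-fraction derivative).  Event-rate calibration uses the
identity that the population-average derivative of a mean-normalised
exponential rate is (log-linear coefficient)×(mean rate); the cost
effect splits 20% prescriptions / 15% appointments / 65% inpatient.
The calibration is exact at the reference point; curvature of the
exponentials leaves the population-average generating effect within a
few percent of the target, well inside estimation noise at the tested
sample sizes.

**Conditions and utilities.** The catalogue holds K = 24 conditions
(a stand-in for the ~240 used with real data — the machinery is
indifferent to K), with decrements drawn once from U(0.02, 0.12) and
10% relative SEs.  The first four are named for the restricted set
conventional decision models use (cancer, cardiovascular disease,
cerebrovascular disease, type 2 diabetes).  Conditions are independent
given BMI and the confounder; real comorbidity clustering is not
emulated.

**Missingness.** A fraction 1 − 0.31 of people lose their QALY and
primary-cost outcomes (the published primary-care linkage rate), MCAR
by default, optionally MAR with logistic dependence on age
(recalibrated to preserve marginal coverage).

**Seeding.** One master seed feeds named substreams (genotypes,
confounder, BMI, covariates, ledger, annual, missingness); cohorts are
bit-identical under a fixed seed and stages can be regenerated
independently.

## Outcome construction (`mrcea.outcomes`)

Day-count conventions: 365-day years, 0-based day offsets from
recruitment, half-open intervals, condition onset day inclusive,
utility 0 from the death day onward.  Daily utility is
`baseline(age, sex) − Σ decrements(active conditions)`, clamped at a
floor of −0.594 (states worse than death are allowed, as in EQ-5D
tariffs); the additive-with-clamp form is the default (a multiplicative
combination is a plausible alternative; additive was chosen for
transparency and testability).  QALYs/year is the unweighted mean of
per-year mean utilities, a partial final year averaged over its own
length.  `person_qalys` computes this exactly in O(#events) by interval
arithmetic and is tested to agree to 1e-12 with the O(#days) daily
profile.

Costs: primary = Σ(drug tariff + £1.27 dispensing fee) + £30 per
appointment, divided by primary follow-up years; secondary = inpatient
episode costs × 1.0484 (cost-inflation to Nov-2019 prices), divided by
secondary follow-up years (two fewer than primary); total = primary +
secondary.  Prescriptions with no tariff match are excluded and
counted, not imputed, mirroring the ~94% costed coverage typical of
tariff matching.

## Main analysis (`mrcea.mr`)

2SLS is solved directly from the just-identified moment condition
`(Z'W)b = Z'y` with `W = [X, C]`, `Z = [instrument, C]`; the sandwich
variance uses structural residuals with the HC1 small-sample factor
(the robust-SE default of the standard IV software).  Centre enters as
one-hot indicators, first level dropped; collinear covariates raise an
error naming the offending columns; rows with missing outcomes are
dropped (imputation handles them upstream).  The first-stage F is the
squared robust t of the instrument.  The Hausman test defaults to the
regression-based control-function form (first-stage residual added to
the outcome model, robust t² against χ²(1)); the classic variance-
contrast form is available and falls back, flagged, when its variance
difference is non-positive.  With a perfect instrument the statistic
is defined as 0.

## Summary-statistic estimators (`mrcea.summary_mr`)

Per-SNP summaries are covariate-adjusted single-SNP regressions,
computed by residualising outcome, exposure and all dosage columns on
the covariates once (shared QR) — verified per-SNP against statsmodels.
IVW is the 1/se² weighted slope through the origin with a
multiplicative random-effects scale max(1, √(Q/(L−1))) (fixed- vs
random-effects is not standardised in the field; multiplicative RE is
the conservative default).  Egger adds a free intercept (mean
directional pleiotropy).  Orientation: sets built from a harmonised
weight table are *not* re-flipped on measured signs — doing so negates
the direct effects of weak SNPs and demonstrably biases the intercept
toward zero; hand-built summary sets are flipped to positive exposure
betas as usual.  The weighted median merges tied ratios before
interpolating; modes use a Gaussian kernel with bandwidth
φ·1.4826·MAD (φ = 1 default) over a 1024-point grid; median/mode SEs
come from a parametric bootstrap (1,000 draws, seeded).  Cochran's Q
uses ratio-scale weights `β_xj²/se_yj²`.  One-sample caveats (NOME,
winner's-curse-free weights) are accepted and shared with common
practice.

## Nonlinear MR (`mrcea.nonlinear`)

PRS-free BMI is the OLS residual of BMI on instrument + covariates
(orthogonal to the instrument by construction, so stratifying on it
cannot induce collider bias).  LACE = 2SLS within each of 10 quantiles
(default; ≥500 people per stratum enforced), each stratum labelled by
its mean observed BMI (the LACE convention, rather than bin
midpoints).  The dose–response curve keeps both representations: the
piecewise-constant per-stratum effects with their support, and a cubic
variance-weighted least-squares fit in stratum mean BMI with
coefficient covariance `(X'WX)^{-1}`; fewer than four strata reduce
the degree with a warning flag.  Confidence bands are pointwise.
Prediction uncertainty in the utility catalogue is propagated by
re-drawing decrements from N(d, se) B = 100 times and pooling the
variance Rubin-style.

## Imputation (`mrcea.imputation`)

Chained equations over the incomplete outcomes: per target, a Bayesian
linear regression on the predictors and the other targets (posterior
draw of σ from the scaled inverse-χ² and of β from its normal), then
predictive mean matching — each missing value takes the observed
outcome of one of the k = 5 nearest observed fitted values (vectorised
as a random offset around the insertion point in the sorted fitted
values).  PMM is the default because costs are strongly right-skewed
and a normal-draw imputer produces implausible negatives; the
normal-draw option is retained for tests.  Ten iterations per dataset;
m defaults to 100 with tests at m = 5.  Rubin's rules give pooled
beta = mean, total variance = within-mean + (1+1/m)·between, with
Barnard–Rubin degrees of freedom; the across-imputation *median* p is
reported alongside for the endogeneity tests, where a pooled χ² is not
well defined.

## Policy engine (`mrcea.policy`)

Interventions: multiplicative BMI reduction (surgery: −25%, CI 22–28%,
£9,549, eligibility BMI ≥ 35, 20-year horizon), calorie reduction
(11–14 kcal/day midpoint 12.5 × 0.042 kg/kcal, converted through
age-band mean height, scalar fallback 1.70 m), quantile-mapping
distribution shift, and a cap-at-threshold counterfactual.  The annual
effect of moving from b₀ to b₁ is `∫_{b₀}^{b₁} β(b) db`, integrated
exactly (polynomial antiderivative, or segment overlap for the
piecewise form).  The piecewise form is the default for policy runs —
stratum estimates are unbiased at the extremes, whereas a cubic is not
trusted outside its fitted range; beyond the curve's support the
boundary effect is extended as a constant.  Over the horizon, bins
advance one year of age annually and switch age-band curves as they
cross boundaries.  Streams are discounted at 3.5%/year; the timing
convention defaults to first-year-undiscounted (exponents 0…H−1), with
end-of-year (1…H) exposed — published analyses of this kind rarely
state the convention, so both are labelled in outputs.
`NMB = λ·ΔQALY_pv − ΔCost_pv − intervention cost` at λ = £20,000/QALY;
the identity is asserted on every emitted result.  Uncertainty:
Monte-Carlo draws of the smooth coefficients from their multivariate
normal, the piecewise effects from their per-stratum normals, and the
surgery fraction from its CI-implied normal; 2.5/97.5 percentiles over
1,000 draws (seeded).  The bundled 1993/2017 England-&-Wales
population distributions are *synthetic* lognormal reconstructions
from summary shapes (total 21,742,497 adults aged 40–69, ~12.6% above
BMI 35, ~72% above 25); only the published totals are taken as given.

## Orchestration (`mrcea.pipeline`, `mrcea.cli`)

The `mrcea` CLI exposes `simulate`, `outcomes`, `mr`, `sensitivity`,
`nonlinear`, `impute`, `policy` and `all`; each stage command runs the
pipeline up to and including that stage (later stages consume earlier
in-memory products).  Every run writes CSV tables plus a JSON manifest
(seed, config hash, stage timings, row counts, package versions).  CSV
is the interchange format throughout; YAML for configs; an optional
VCF reader (cyvcf2) ingests GT-based dosages.  The default demo
configuration (n = 5,000) completes in well under a minute on one CPU.

## Problem sizes and determinism

Simulation studies in the test suite and acceptance script use
n = 20,000 cohorts and 80–200 replicates — sizes at which every
qualitative property under test (coverage, bias direction, recovery
within stated tolerances) is comfortably resolved while a full run of
suite plus script stays within a few minutes on a single CPU.  All
stochastic tests fix their seeds, so reported pass/fail states are
reproducible exactly.

## Known limitations

- No LD, relatedness, assortative mating or population structure in the
  generator; within-family designs are out of scope.
- Conditions are conditionally independent given BMI and the
  confounder; no comorbidity clustering or condition-specific mortality.
- The ledger channel supports scalar true effects only; nonlinear
  truths and pleiotropy live in the annual channel.
- One-sample summary-MR approximations (NOME; shared-sample weights).
- Policy results depend on the synthetic population distributions; with
  real survey distributions the engine is unchanged but the numbers are
  not comparable.
- No dynamic BMI trajectories, weight regain, or mortality-driven
  population renewal over the policy horizon.
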