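# Methods notes

## Estimands and estimators

The pipeline targets the multiplicative decomposition `TE = NDE x NIE` of
the effect of binary low SES on binary incident disease, with the seven
behavioural/metabolic mediators treated as a single joint block. Three
counterfactual mean risks identify the decomposition:

* factual means `E[Y(1, L1, M1)]` and `E[Y(0, L0, M0)]` — estimated as the
  IPW-weighted mean outcome within each exposure group, identical to the
  predictions of a weighted saturated Poisson model of Y on exposure;
* the cross-world mean `E[Y(1, L0, M0)]` — a weighted modified-Poisson model
  of Y on exposure, mediators, confounders and exposure x mediator products,
  evaluated with exposure set to 1 on the unexposed records and averaged
  with their stabilized weights. The stabilized weights reweight the
  unexposed to the marginal confounder distribution, so this weighted
  average standardizes the mediator-confounder law correctly; the test-suite
  pins this against exhaustive g-computation on an enumerated population.

Pooling all mediators into one indirect effect avoids double-counting
pathways that run through several correlated mediators; the price is that no
per-mediator path decomposition is available (deliberately out of scope).

Identification assumes no unmeasured exposure-outcome or mediator-outcome
confounding given `c`, positivity, and consistency. E-values report how
strong a violation of the first assumption would need to be.

## Proportion mediated

`PM = log NIE / log TE`. Division on the log scale is the coherent choice
for a multiplicative decomposition (the shares of NDE and NIE then sum to
1); the excess-relative-risk alternative `NDE (NIE - 1) / (TE - 1)` is
available via `proportion_mediated(..., scale="rr_minus_one")`. PM is
reported as NaN when TE = 1 (nothing to apportion).

## Traditional methods on the risk-ratio scale

The classical difference and product-of-coefficients constructions are
written for linear models; here the outcome models are log-link Poisson
fits so that all three methods report risk ratios. For the product method
the binary mediator models use a logit link, and the exposure coefficient
entering each product is standardized to the probability scale: the
model-implied average marginal effect of the exposure on `P(M_j = 1)`
(a risk difference in prevalence). The product `gamma_j x mu_j` (prevalence
shift x log-RR per unit of mediator) is then a log-RR contribution on
exactly the scale of `alpha_x - beta_x`, which is what cross-method
comparability requires. For rare outcomes and modest effects the two
constructions agree to first order; the suite checks agreement within 5
percentage points of PM at n = 50 000, and exact equality in the
linear-Gaussian case where the classical algebra is exact.

## Weights

Propensities come from a maximum-likelihood logistic model (the link is a
package choice; the source analysis does not name one). No truncation is
applied by default; symmetric percentile truncation is available and
recorded in the WeightSet when used. Propensity estimates within 1e-8 of
0/1, or a propensity model driven to the boundary by a covariate pattern
with a single exposure level, raise positivity errors rather than emitting
extreme weights. Stabilization makes the mean weight ~1; this is asserted
(within [0.9, 1.1]) on well-specified simulations.

## GLM engine

Fitting is a compact IRLS loop (canonical links: log-Poisson, logit,
identity) with step-halving and an HC0 sandwich covariance in which the
observation weights enter the score squared (the fixed-weight IPW
convention). Convergence is declared on coefficient stability (1e-10) or on
a converged deviance — the latter matters when a covariate cell contains no
events and its coefficient legitimately runs to -infinity while every
fitted mean converges. Collinear designs raise an error naming the aliased
terms; inside bootstrap replicates, columns that become constant in a
resample are dropped instead (a vanished term contributes nothing to the
replicate's model). Coefficients and sandwich SEs are cross-validated
against statsmodels GLM in the tests; statsmodels is deliberately kept as
an independent oracle rather than the execution path, because the bootstrap
re-fits every model per replicate and the coverage simulations re-run the
bootstrap hundreds of times.

## Bootstrap

Percentile intervals (2.5/97.5) from B resamples of individuals; every
replicate re-estimates the sex-specific alcohol terciles, the propensity
model, the weights and both outcome models, so all estimation uncertainty
propagates. Replicate b draws its stream from SeedSequence([master, b]):
enlarging B never perturbs earlier replicates. Replicates that fail
estimation are logged and excluded; a failure rate above 5% invalidates the
run. The decomposition identity TE = NDE x NIE holds exactly within every
replicate by construction.

## Synthetic cohort generator

Structure: confounders (truncated-normal age on [35, 60], Bernoulli sex,
logit-linear family history / comorbidity / poor health) -> logit-linear
binary exposure -> logit-linear mediators (behavioural first, then
metabolic, which may load on the behavioural block) -> log-link outcome.
The log link keeps the ground truth on the risk-ratio scale the estimators
target; risks are capped at 0.99 with an exposed clamp counter, and the
default configuration is constructed so the analytic supremum of the
log-risk stays below log(0.99) — the counter must read 0.

Intercepts are calibrated by root-finding on a fixed large reference draw
so each marginal matches its target: the cohort's descriptive-table
prevalences (smoking 25.3%, obesity 11.9%, high fasting glucose 5.1%,
hypertension 13.0%, outcome 18.4%, low education 18.5%, ...). Slope
coefficients were chosen to reproduce the descriptive table's
exposed/unexposed prevalence gaps and a total effect of realistic size
(truth at the default: TE 1.24, NDE 1.12, NIE 1.11, PM 50%).

Raw measurements are emitted alongside the latent binaries so the
dichotomizers are exercised end to end: BMI, fasting glucose and blood
pressures are drawn from truncated normals on the correct side of the
clinical cut-points (recovery of the latent state is exact); activity and
food-frequency ordinals are drawn within the level sets their latent
implies. Alcohol is the one re-estimated cut-point: the latent
"high consumption" targets prevalence 1/3 per sex and the continuous cl/day
values are drawn on the matching side of fixed design cut-points, so the
empirical sex-specific tercile lands near the design value and
reclassifies only an O(n^-1/2) boundary fraction. The cohort that motivated
the schema prints 19.4% high alcohol — an artefact of tie/zero structure in
self-reports that the generator does not emulate; a tercile rule on
continuous data pins the share near one third, so 1/3 is the generator's
own target.

Exclusion flags (prevalent disease, missing SES, missing covariates,
type-1/LADA, emigration, death) are independent Bernoullis with rates
matching the source cohort's counts out of 7948; they are data-cleaning
noise, not part of the causal model. A record with several flags is tallied
under the first reason in the stated order (the published counts are not
additive, so some such rule must be chosen).

Ground truth: `true_effects` draws confounders once, draws mediators under
exposure 1 and under exposure 0 with common uniforms (monotone coupling),
and averages the outcome model's risk — never a Bernoulli draw — under the
three regimes, including the cross-world one. Coupling makes NIE exactly 1
when no mediator model depends on exposure, and shrinks the Monte-Carlo
error of the ratios; delta-method MC standard errors are reported.

What the generator does not emulate: time-varying mediators or competing
risks; measurement error in self-reports; occupational class as an
independent cause. Occupation is generated as a second SES measure
correlated with education (logit on education and confounders) but without
its own mediator/outcome coefficients — giving it independent causal paths
would make it an unmodelled mediator of the education analysis and
invalidate the recovery benchmark. Occupation-exposure runs on the default
cohort therefore come out near-null once education is adjusted for (which
the pipeline does by default, adding low education to the confounder set
for occupation analyses, including its sex-stratified cells). Passing tests
demonstrate correctness of the estimators under the stated structure, not
robustness to real-data features outside it.

## Dichotomization rules

Low education = basic education only ("lower than upper secondary"; the
middle category bundles vocational with upper secondary). Low occupation =
unskilled + semiskilled manual workers. High alcohol = strictly above the
sex-specific empirical 2/3-quantile (linear interpolation) — strict
inequality keeps the high group <= 1/3 under ties. Low activity = the two
lowest of five self-rated levels. Low fruit/vegetable intake = once per
week or more seldom. Obesity = BMI >= 30 (boundary inclusive); high fasting
glucose = FPG >= 5.6 mmol/l; hypertension = SBP >= 140 OR DBP >= 90 OR
antihypertensive use (the standard reading of "140/90"). Missingness is
carried by explicit flags and resolved by exclusion, never by sentinel
values; a missing required field at dichotomization time is an error naming
the field.

## Interaction terms

The cross-world model includes the full exposure x mediator product set by
default; mediator x mediator products are accepted as an explicit list.
Inclusion is configuration-driven, not significance-driven — screening by
p-value inside a bootstrap would make the replicate models incomparable.

## Problem sizes used in the test-suite

Enumeration oracles run on a 200-row exact population. Parameter-recovery
checks use cohorts of n = 50 000 against a 10^6-draw Monte-Carlo truth
(tolerance 0.03 on the log-RR scale, ~2 MC + sampling SDs). Interval
calibration uses 100 cohorts of n = 2000 with B = 200 (coverage asserted in
[90%, 99%], the two-sided binomial band for a 95% interval). Method
agreement uses a rare-outcome (4% baseline) generator at n = 50 000,
tolerance 5 pp of PM. These sizes keep every check's Monte-Carlo error well
inside its tolerance.

## Known limitations

* Single time-point exposure and mediators; no time-varying weights.
* Complete-case analysis only (matching the source design); no imputation.
* The product method's standardization has no canonical definition for
  binary mediators; the probability-scale recipe here is validated through
  the rare-outcome agreement property, not against an external standard.
* PM is intrinsically noisy at cohort sizes of a few thousand (wide
  bootstrap intervals are the honest output, not a defect).
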