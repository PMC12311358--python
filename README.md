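# sesmediate

Counterfactual and traditional mediation analysis of socioeconomic
inequalities in type 2 diabetes incidence.

## The problem

Adults with low socioeconomic status (SES) — measured by educational
attainment or occupational class — develop type 2 diabetes more often than
their better-off peers. How much of that excess risk travels through the
usual targets of prevention programmes (smoking, high alcohol intake, low
physical activity, a diet low in fruit and vegetables, obesity, high fasting
glucose, hypertension), and how much is a direct effect of social position
itself? The answer decides whether levelling individual-level risk factors
could close the gap.

This package implements the full analysis pipeline for that question on a
cohort table (one row per participant), together with a synthetic cohort
generator whose ground truth is known, so every stage is testable without
access to the original registry-linked data.

## The model

Let `x` be binary low SES (`x* = 0` otherwise), `c` confounders (age, sex,
family history of diabetes, comorbidity, poor self-rated health), `L` four
behavioural and `M` three metabolic binary mediators, and `Y` incident
disease. Stabilized inverse-probability-of-exposure weights

    IPW = P(x=1) / P(x=1|c)      if exposed
    IPW = (1-P(x=1)) / (1-P(x=1|c))  otherwise

feed weighted modified-Poisson (log-link, robust-variance) marginal
structural models, from which three counterfactual mean risks are estimated:
`E[Y_x L_x M_x]`, `E[Y_x* L_x* M_x*]`, and the cross-world mean
`E[Y_x L_x* M_x*]` (exposed, but mediators following their unexposed law,
by g-computation). On the risk-ratio scale

    TE_RR = NDE_RR x NIE_RR
    TE  = E[Y_x L_x M_x] / E[Y_x* L_x* M_x*]
    NDE = E[Y_x L_x* M_x*] / E[Y_x* L_x* M_x*]
    NIE = E[Y_x L_x M_x] / E[Y_x L_x* M_x*]

with all seven mediators treated jointly, proportion mediated
`PM = log NIE / log TE`, and percentile bootstrap intervals that re-run the
entire pipeline (tercile cut-offs, propensity model, weights, outcome
models) in each replicate. The difference method (`exp(alpha_x)`,
`exp(beta_x)`, `exp(alpha_x - beta_x)`) and the product-of-coefficients
method (per-mediator `gamma_x,j * mu_j`, summed) are implemented on the same
scale for comparison, and E-values `E = RR + sqrt(RR(RR-1))` quantify
robustness to unmeasured confounding.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # cohort + Monte-Carlo ground truth
python analysis/02_prepare_cohort.py       # exclusions, terciles, dichotomization
python analysis/03_adjusted_models.py      # progressively adjusted RR models
python analysis/04_mediation_decomposition.py   # 2 x 3 x 3 decomposition grid
python analysis/05_evalue_sensitivity.py   # E-values for every estimate
```

The first two stages print (seed 0):

```
cohort: n=7948, risk clamps=0
ground truth: TE=1.244  NDE=1.116  NIE=1.114  PM=49.6%
excluded 815 of 7948: {'prevalent_t2d': 140, 'missing_ses': 29,
 'missing_covariates': 126, 't1d_or_lada': 23, 'emigrated': 121, 'died': 376}
analysis set: n=7133 (4346 women, 2787 men)
```

i.e. in the generating model low education raises diabetes risk 24% in
total, about half of it through the seven mediators. The decomposition stage
then estimates, for the education exposure on this single cohort:

```
education  counterfactual TE 1.36 (1.20,1.51)  NDE 1.26  NIE 1.08  PM 25.0%
education  difference     TE 1.37 (1.22,1.52)  NDE 1.22  NIE 1.12  PM 36.4%
education  product        TE 1.36 (1.22,1.49)  NDE 1.22  NIE 1.11  PM 34.9%
```

All three methods agree within sampling error, and the bootstrap PM interval
for the counterfactual method (7.4%, 51.6%) covers the true 49.6% — at
n ≈ 7000 the proportion mediated is estimated with substantial uncertainty,
which is exactly why the test-suite checks recovery at n = 50 000 and
interval calibration over repeated cohorts. Finally:

```
education  te  RR 1.36 -> E-value 2.05 (CI limit 1.68)
```

an unmeasured confounder would need risk-ratio associations of about 2 with
both exposure and outcome to explain the total effect away.

## Layout

    src/sesmediate/   library: simulate, prep, weights, glm, mediation,
                      traditional, evalues, pipeline
    analysis/         numbered narrative drivers (thin wrappers over src/)
    tests/            pytest suite, including enumeration oracles and
                      coverage simulations
    docs/methods.md   modelling and design notes
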