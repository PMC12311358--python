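"""Synthetic cohort generator with Monte-Carlo ground-truth effects.

The generator emulates a middle-aged Swedish screening cohort followed for
incident type 2 diabetes: confounders (age, sex, family history, comorbidity,
poor self-rated health) influence a binary low-SES exposure, seven binary
risk-factor mediators (four behavioural, three metabolic) and the outcome;
the exposure influences the mediators and the outcome; the behavioural
mediators may feed the metabolic ones.  All structural equations are
logit-linear except the outcome, which uses a log link so that the ground
truth lives on the risk-ratio scale the estimators target.

Alongside each latent binary mediator the generator emits the raw
measurement it would have been derived from (alcohol in cl/day, BMI, fasting
glucose, blood pressures, ordinal activity and food-frequency levels), so
the preparation stage's dichotomizers can be exercised end to end.

``true_effects`` computes the total, natural direct and natural indirect
risk ratios by Monte-Carlo g-computation: confounders are drawn once,
mediators are drawn under exposure set to 1 and to 0 (coupled through common
uniforms), and the outcome model is evaluated — never sampled — under the
three counterfactual regimes, including the cross-world one (exposed, but
mediators following their unexposed law).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigError

SEX_LEVELS = ("female", "male")
EDUCATION_LEVELS = ("basic", "vocational_or_upper_secondary", "university")
OCCUPATION_LEVELS = (
    "unskilled",
    "semiskilled",
    "skilled",
    "assistant_nonmanual",
    "employed_professional",
    "self_employed_professional",
    "higher_civil_servant",
)
LOW_OCCUPATION_LEVELS = ("unskilled", "semiskilled")
PA_LEVELS = ("much_lower", "lower", "average", "higher", "much_higher")
FFQ_LEVELS = (
    "never",
    "1_2_per_month",
    "1_per_week",
    "2_3_per_week",
    "4_6_per_week",
    "1_per_day",
    "2_3_per_day",
    "gt4_per_day",
)
BEHAVIOURAL = ("smoking", "high_alcohol", "low_physical_activity", "low_fruitveg")
METABOLIC = ("obesity", "high_fpg", "hypertension")
MEDIATORS = BEHAVIOURAL + METABOLIC
CONFOUNDER_BINARIES = ("family_history", "comorbidity", "poor_health")
EXCLUSION_REASONS = (
    "prevalent_t2d",
    "missing_ses",
    "missing_covariates",
    "t1d_or_lada",
    "emigrated",
    "died",
)

#: Frozen column dictionary of the cohort CSV.  ``latent_*`` columns carry the
#: generator's binary states so the dichotomizers can be validated; a real
#: cohort file would simply omit them.
COHORT_COLUMNS = (
    ["id", "age", "sex", "education_level", "occupational_class"]
    + list(CONFOUNDER_BINARIES)
    + [
        "smoker_current",
        "alcohol_cl_day",
        "physical_activity",
        "fruitveg_freq",
        "bmi",
        "fpg",
        "sbp",
        "dbp",
        "antihypertensive_use",
        "incident_t2d",
    ]
    + list(EXCLUSION_REASONS)
    + [f"latent_{m}" for m in MEDIATORS if m != "smoking"]
    + ["latent_low_education", "latent_low_occupation"]
)


@dataclass
class LogitModel:
    """Bernoulli structural equation: P = expit(intercept + coef . covariates)."""

    intercept: float = 0.0
    coef: dict[str, float] = field(default_factory=dict)


@dataclass
class OutcomeModel:
    """Log-link risk equation; ``interactions`` keys look like ``"x:smoking"``."""

    intercept: float = -2.0
    coef: dict[str, float] = field(default_factory=dict)
    interactions: dict[str, float] = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    n: int = 7948
    seed: int = 0
    age_mean: float = 47.0
    age_sd: float = 4.9
    age_lo: float = 35.0
    age_hi: float = 60.0
    p_female: float = 0.615
    confounder_models: dict[str, LogitModel] = field(default_factory=dict)
    exposure_model: LogitModel = field(default_factory=LogitModel)
    occupation_model: LogitModel = field(default_factory=LogitModel)
    mediator_models: dict[str, LogitModel] = field(default_factory=dict)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    risk_cap: float = 0.99
    exclusion_probs: dict[str, float] = field(default_factory=dict)
    # raw-measurement emission: sex-specific design cut-points for alcohol
    alcohol_cut_female: float = 1.17
    alcohol_cut_male: float = 2.33
    edu_mid_share: float = 0.55  # vocational share among the non-low-educated


@dataclass
class OracleTruth:
    """Monte-Carlo ground truth for a generator configuration."""

    te_rr: float
    nde_rr: float
    nie_rr: float
    pm: float  # log-scale proportion mediated; NaN when TE = 1
    mc_n: int
    mc_se: dict[str, float]
    means: dict[str, float]
    n_clamped: int

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# validation

def _check_prob(name, p):
    if not (0.0 < p < 1.0):
        raise ConfigError(f"{name} must lie in (0, 1); got {p}")


def validate_config(config: GeneratorConfig) -> None:
    """Raise ConfigError naming the offending parameter."""
    if not isinstance(config.n, (int, np.integer)) or config.n < 1:
        raise ConfigError(f"n must be a positive integer; got {config.n}")
    _check_prob("p_female", config.p_female)
    if config.age_sd <= 0:
        raise ConfigError(f"age_sd must be positive; got {config.age_sd}")
    if config.age_lo >= config.age_hi:
        raise ConfigError("age_lo must be below age_hi")
    if not (0.0 < config.risk_cap <= 1.0):
        raise ConfigError(f"risk_cap must lie in (0, 1]; got {config.risk_cap}")
    for reason, p in config.exclusion_probs.items():
        if reason not in EXCLUSION_REASONS:
            raise ConfigError(f"unknown exclusion reason {reason!r}")
        if not (0.0 <= p < 1.0):
            raise ConfigError(f"exclusion_probs[{reason!r}] must lie in [0, 1); got {p}")
    for name in config.mediator_models:
        if name not in MEDIATORS:
            raise ConfigError(f"unknown mediator {name!r}")


def max_log_risk(config: GeneratorConfig) -> float:
    """Analytic supremum of the outcome log-risk over the covariate space.

    Every structural covariate is binary except centred age; the supremum is
    the intercept plus each coefficient's most adverse achievable
    contribution.  A valid default configuration keeps this below
    log(risk_cap) so that no draw is ever clamped.
    """
    om = config.outcome_model
    total = om.intercept
    age_rng = (config.age_lo - config.age_mean, config.age_hi - config.age_mean)
    for name, c in om.coef.items():
        if name == "age_c":
            total += max(c * age_rng[0], c * age_rng[1])
        else:
            total += max(0.0, c)
    for _, c in om.interactions.items():
        total += max(0.0, c)
    return total


# ---------------------------------------------------------------------------
# structural draws

def _linpred(intercept, coef, table):
    s = np.full_like(next(iter(table.values()), np.zeros(1)), intercept, dtype=float)
    for k, c in coef.items():
        s = s + c * table[k]
    return s


def _draw_confounders(config, n, rng):
    a = (config.age_lo - config.age_mean) / config.age_sd
    b = (config.age_hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    female = (rng.random(n) < config.p_female).astype(float)
    table = {"age_c": age - config.age_mean, "female": female, "age": age}
    for name in CONFOUNDER_BINARIES:
        model = config.confounder_models.get(name, LogitModel())
        p = expit(_linpred(model.intercept, model.coef, table))
        table[name] = (rng.random(n) < p).astype(float)
    return table


def _mediator_prob(config, name, table):
    model = config.mediator_models.get(name, LogitModel())
    return expit(_linpred(model.intercept, model.coef, table))


def _outcome_risk(config, table):
    om = config.outcome_model
    lin = _linpred(om.intercept, om.coef, table)
    for key, c in om.interactions.items():
        a, b = key.split(":")
        lin = lin + c * table[a] * table[b]
    risk = np.exp(lin)
    clamped = int(np.sum(risk > config.risk_cap))
    return np.minimum(risk, config.risk_cap), clamped


# ---------------------------------------------------------------------------
# raw-measurement emission

def _tn(rng, lo, hi, loc, scale, size):
    return truncnorm.rvs((lo - loc) / scale, (hi - loc) / scale, loc=loc, scale=scale,
                         size=size, random_state=rng)


def _emit_raw(config, table, rng):
    n = len(table["female"])
    out = {}
    out["smoker_current"] = table["smoking"].astype(int)

    cut = np.where(table["female"] == 1.0, config.alcohol_cut_female, config.alcohol_cut_male)
    hi_draw = cut + np.abs(_tn(rng, 0.0, 5.0, 0.7, 0.9, n))
    lo_cont = np.clip(_tn(rng, 0.01, 1.0, 0.45, 0.35, n), 0.01, None) * cut
    zero = rng.random(n) < 0.25
    lo_draw = np.where(zero, 0.0, lo_cont)
    out["alcohol_cl_day"] = np.where(table["high_alcohol"] == 1.0, hi_draw, lo_draw)

    low_pa = table["low_physical_activity"] == 1.0
    pa = np.empty(n, dtype=object)
    u = rng.random(n)
    pa[low_pa] = np.where(u[low_pa] < 0.30, "much_lower", "lower")
    rest = ~low_pa
    pa[rest] = np.select(
        [u[rest] < 0.60, u[rest] < 0.90], ["average", "higher"], default="much_higher"
    )
    out["physical_activity"] = pa

    low_fv = table["low_fruitveg"] == 1.0
    fv = np.empty(n, dtype=object)
    u = rng.random(n)
    fv[low_fv] = np.select(
        [u[low_fv] < 0.20, u[low_fv] < 0.55], ["never", "1_2_per_month"], default="1_per_week"
    )
    fv[~low_fv] = np.select(
        [u[~low_fv] < 0.35, u[~low_fv] < 0.65, u[~low_fv] < 0.85, u[~low_fv] < 0.97],
        ["2_3_per_week", "4_6_per_week", "1_per_day", "2_3_per_day"],
        default="gt4_per_day",
    )
    out["fruitveg_freq"] = fv

    obese = table["obesity"] == 1.0
    out["bmi"] = np.where(
        obese, _tn(rng, 30.0, 48.0, 32.2, 2.2, n), _tn(rng, 16.5, 29.999, 25.0, 2.9, n)
    )
    high_fpg = table["high_fpg"] == 1.0
    out["fpg"] = np.where(
        high_fpg, _tn(rng, 5.6, 9.5, 5.9, 0.45, n), _tn(rng, 3.2, 5.599, 4.67, 0.42, n)
    )

    htn = table["hypertension"] == 1.0
    med = htn & (rng.random(n) < 0.35)
    u = rng.random(n)
    sbp_only = htn & ~med & (u < 0.45)
    both = htn & ~med & (u >= 0.45) & (u < 0.75)
    dbp_only = htn & ~med & (u >= 0.75)
    sbp = _tn(rng, 92.0, 139.9, 120.0, 11.0, n)  # normotensive / controlled default
    dbp = _tn(rng, 55.0, 89.9, 75.5, 8.0, n)
    sbp = np.where(med, _tn(rng, 100.0, 139.9, 128.0, 8.0, n), sbp)
    dbp = np.where(med, _tn(rng, 60.0, 89.9, 80.0, 6.0, n), dbp)
    sbp = np.where(sbp_only | both, _tn(rng, 140.0, 210.0, 150.0, 9.0, n), sbp)
    dbp = np.where(both | dbp_only, _tn(rng, 90.0, 120.0, 93.5, 3.5, n), dbp)
    sbp = np.where(dbp_only, _tn(rng, 100.0, 139.9, 131.0, 6.0, n), sbp)
    out["sbp"], out["dbp"] = sbp, dbp
    out["antihypertensive_use"] = med.astype(int)
    return out


# ---------------------------------------------------------------------------
# public operations

def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a pre-exclusion cohort as a DataFrame with the frozen schema.

    The number of risk clamps applied by the log-link outcome model is
    exposed as ``df.attrs["n_risk_clamped"]`` (0 for valid configurations).
    """
    validate_config(config)
    n = config.n
    rng = np.random.default_rng(config.seed if seed is None else seed)
    table = _draw_confounders(config, n, rng)

    p_x = expit(_linpred(config.exposure_model.intercept, config.exposure_model.coef, table))
    table["x"] = (rng.random(n) < p_x).astype(float)
    p_occ = expit(_linpred(config.occupation_model.intercept, config.occupation_model.coef, table))
    x_occ = (rng.random(n) < p_occ).astype(float)

    for name in MEDIATORS:
        p = _mediator_prob(config, name, table)
        table[name] = (rng.random(n) < p).astype(float)

    risk, clamped = _outcome_risk(config, table)
    y = (rng.random(n) < risk).astype(int)

    raw = _emit_raw(config, table, rng)

    u = rng.random(n)
    edu = np.where(
        table["x"] == 1.0,
        "basic",
        np.where(u < config.edu_mid_share, "vocational_or_upper_secondary", "university"),
    )
    u = rng.random(n)
    occ = np.empty(n, dtype=object)
    low = x_occ == 1.0
    occ[low] = np.where(u[low] < 0.55, "unskilled", "semiskilled")
    occ[~low] = np.select(
        [u[~low] < 0.28, u[~low] < 0.54, u[~low] < 0.78, u[~low] < 0.86],
        ["skilled", "assistant_nonmanual", "employed_professional",
         "self_employed_professional"],
        default="higher_civil_servant",
    )

    df = pd.DataFrame({
        "id": [f"P{i:06d}" for i in range(n)],
        "age": table["age"],
        "sex": np.where(table["female"] == 1.0, "female", "male"),
        "education_level": edu,
        "occupational_class": occ,
    })
    for name in CONFOUNDER_BINARIES:
        df[name] = table[name].astype(int)
    for k in ["smoker_current", "alcohol_cl_day", "physical_activity", "fruitveg_freq",
              "bmi", "fpg", "sbp", "dbp", "antihypertensive_use"]:
        df[k] = raw[k]
    df["incident_t2d"] = y
    for reason in EXCLUSION_REASONS:
        p = config.exclusion_probs.get(reason, 0.0)
        df[reason] = (rng.random(n) < p).astype(int)
    for m in MEDIATORS:
        if m != "smoking":
            df[f"latent_{m}"] = table[m].astype(int)
    df["latent_low_education"] = table["x"].astype(int)
    df["latent_low_occupation"] = x_occ.astype(int)
    df = df[COHORT_COLUMNS]
    df.attrs["n_risk_clamped"] = clamped
    return df


def true_effects(config: GeneratorConfig, mc_n: int = 1_000_000,
                 seed: int | None = None) -> OracleTruth:
    """Ground-truth TE/NDE/NIE risk ratios by Monte-Carlo g-computation.

    Mediators under the exposed and unexposed regimes share common uniforms
    (monotone coupling), which makes the cross-world consistency property —
    NIE exactly 1 when no mediator model depends on the exposure — hold
    path-wise, and shrinks the Monte-Carlo error of the ratios.
    """
    validate_config(config)
    if seed is None:
        seed = np.random.SeedSequence([config.seed, 101]).generate_state(1)[0] % (2**31)
    rng = np.random.default_rng(seed)
    table = _draw_confounders(config, mc_n, rng)

    med1, med0 = {}, {}
    for name in MEDIATORS:
        u = rng.random(mc_n)
        t1 = {**table, "x": np.ones(mc_n), **med1}
        t0 = {**table, "x": np.zeros(mc_n), **med0}
        med1[name] = (u < _mediator_prob(config, name, t1)).astype(float)
        med0[name] = (u < _mediator_prob(config, name, t0)).astype(float)

    r_xx, c1 = _outcome_risk(config, {**table, "x": np.ones(mc_n), **med1})
    r_ss, c2 = _outcome_risk(config, {**table, "x": np.zeros(mc_n), **med0})
    r_xs, c3 = _outcome_risk(config, {**table, "x": np.ones(mc_n), **med0})

    m = np.array([r_xx.mean(), r_ss.mean(), r_xs.mean()])
    cov = np.cov(np.vstack([r_xx, r_ss, r_xs])) / mc_n
    te, nde, nie = m[0] / m[1], m[2] / m[1], m[0] / m[2]

    def _se(grad):
        g = np.asarray(grad)
        return float(np.sqrt(max(g @ cov @ g, 0.0)))  # guard float cancellation

    mc_se = {
        "log_te": _se([1 / m[0], -1 / m[1], 0.0]),
        "log_nde": _se([0.0, -1 / m[1], 1 / m[2]]),
        "log_nie": _se([1 / m[0], 0.0, -1 / m[2]]),
    }
    log_te = np.log(te)
    pm = float(np.log(nie) / log_te) if abs(log_te) > 1e-9 else float("nan")
    return OracleTruth(
        te_rr=float(te), nde_rr=float(nde), nie_rr=float(nie), pm=pm,
        mc_n=mc_n, mc_se=mc_se,
        means={"m_xx": float(m[0]), "m_ss": float(m[1]), "m_xs": float(m[2])},
        n_clamped=c1 + c2 + c3,
    )


# ---------------------------------------------------------------------------
# calibration and stock configurations

#: Marginal prevalence targets for the default configuration, taken from the
#: cohort's descriptive table.  High alcohol targets 1/3 because the analysis
#: defines it by sex-specific terciles, which pins the share near one third
#: for continuous consumption data.
DEFAULT_TARGETS = {
    "family_history": 0.525,
    "comorbidity": 0.275,
    "poor_health": 0.020,
    "exposure": 0.1846,
    "occupation": 0.2933,
    "smoking": 0.2534,
    "high_alcohol": 1.0 / 3.0,
    "low_physical_activity": 0.2418,
    "low_fruitveg": 0.4099,
    "obesity": 0.1193,
    "high_fpg": 0.0505,
    "hypertension": 0.1296,
    "outcome": 0.1836,
}

_CALIB_SEED = 190_337_211


def calibrate_config(config: GeneratorConfig, targets: dict[str, float] | None = None,
                     n_calib: int = 200_000) -> GeneratorConfig:
    """Solve every intercept so each model's marginal matches its target.

    Models are visited in causal order on a fixed large reference draw; each
    solved model is then sampled so downstream linear predictors see realistic
    inputs.  The outcome (log link) intercept has the closed form
    ``log(target) - log(mean(exp(s)))``.
    """
    targets = DEFAULT_TARGETS if targets is None else targets
    rng = np.random.default_rng(_CALIB_SEED)
    n = n_calib

    def solve_logit(model, table, target):
        s = _linpred(0.0, model.coef, table)
        b0 = brentq(lambda b: float(np.mean(expit(b + s))) - target, -30.0, 30.0, xtol=1e-12)
        return replace(model, intercept=float(b0))

    cm = {}
    a = (config.age_lo - config.age_mean) / config.age_sd
    b = (config.age_hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    female = (rng.random(n) < config.p_female).astype(float)
    table = {"age_c": age - config.age_mean, "female": female, "age": age}
    for name in CONFOUNDER_BINARIES:
        model = solve_logit(config.confounder_models.get(name, LogitModel()), table, targets[name])
        cm[name] = model
        table[name] = (rng.random(n) < expit(_linpred(model.intercept, model.coef, table))).astype(float)

    exposure_model = solve_logit(config.exposure_model, table, targets["exposure"])
    table["x"] = (rng.random(n) < expit(_linpred(exposure_model.intercept, exposure_model.coef, table))).astype(float)
    occupation_model = solve_logit(config.occupation_model, table, targets["occupation"])

    mm = {}
    for name in MEDIATORS:
        model = solve_logit(config.mediator_models.get(name, LogitModel()), table, targets[name])
        mm[name] = model
        table[name] = (rng.random(n) < expit(_linpred(model.intercept, model.coef, table))).astype(float)

    om = config.outcome_model
    lin = _linpred(0.0, om.coef, table)
    for key, c in om.interactions.items():
        k1, k2 = key.split(":")
        lin = lin + c * table[k1] * table[k2]
    b0 = float(np.log(targets["outcome"]) - np.log(np.mean(np.exp(lin))))
    outcome_model = replace(om, intercept=b0)

    return replace(
        config,
        confounder_models=cm,
        exposure_model=exposure_model,
        occupation_model=occupation_model,
        mediator_models=mm,
        outcome_model=outcome_model,
    )


def _base_uncalibrated() -> GeneratorConfig:
    """Default structural coefficients (intercepts solved by calibration)."""
    return GeneratorConfig(
        exposure_model=LogitModel(coef={
            "age_c": 0.04, "female": -0.30, "family_history": 0.25,
            "comorbidity": 0.12, "poor_health": 0.50,
        }),
        occupation_model=LogitModel(coef={
            "x": 1.20, "age_c": -0.02, "female": -0.28, "family_history": 0.20,
            "comorbidity": 0.20, "poor_health": 0.55,
        }),
        mediator_models={
            "smoking": LogitModel(coef={"x": 0.80, "female": -0.05}),
            "high_alcohol": LogitModel(coef={"x": 0.16}),
            "low_physical_activity": LogitModel(coef={"x": 0.31, "comorbidity": 0.35,
                                                      "poor_health": 0.60}),
            "low_fruitveg": LogitModel(coef={"x": 0.26, "female": -0.35}),
            "obesity": LogitModel(coef={"x": 0.70, "low_physical_activity": 0.25,
                                        "low_fruitveg": 0.15, "family_history": 0.15}),
            "high_fpg": LogitModel(coef={"x": 0.70, "low_physical_activity": 0.20,
                                         "family_history": 0.30, "age_c": 0.03}),
            "hypertension": LogitModel(coef={"x": 0.24, "high_alcohol": 0.30,
                                             "low_physical_activity": 0.20,
                                             "age_c": 0.06, "female": -0.15}),
        },
        outcome_model=OutcomeModel(coef={
            "x": 0.11, "smoking": 0.22, "high_alcohol": 0.04,
            "low_physical_activity": 0.10, "low_fruitveg": 0.08,
            "obesity": 0.35, "high_fpg": 0.33, "hypertension": 0.18,
            "age_c": 0.010, "female": -0.10, "family_history": 0.28,
            "comorbidity": 0.08, "poor_health": 0.12,
        }),
        exclusion_probs={
            "prevalent_t2d": 128 / 7948,
            "missing_ses": 28 / 7948,
            "missing_covariates": 134 / 7948,
            "t1d_or_lada": 17 / 7948,
            "emigrated": 127 / 7948,
            "died": 393 / 7948,
        },
    )


@lru_cache(maxsize=1)
def default_config() -> GeneratorConfig:
    """The calibrated default configuration (cached; deterministic)."""
    return calibrate_config(_base_uncalibrated())


def null_config(n: int = 50_000, seed: int = 0, baseline_risk: float = 0.10) -> GeneratorConfig:
    """All structural paths zero: exposure, mediators and outcome independent."""
    logit = lambda p: float(np.log(p / (1 - p)))
    return GeneratorConfig(
        n=n, seed=seed,
        confounder_models={name: LogitModel(intercept=logit(p)) for name, p in
                           [("family_history", 0.525), ("comorbidity", 0.275),
                            ("poor_health", 0.02)]},
        exposure_model=LogitModel(intercept=logit(0.1846)),
        occupation_model=LogitModel(intercept=logit(0.2933)),
        mediator_models={m: LogitModel(intercept=logit(DEFAULT_TARGETS[m])) for m in MEDIATORS},
        outcome_model=OutcomeModel(intercept=float(np.log(baseline_risk))),
        exclusion_probs={},
    )


def fully_mediated_config() -> GeneratorConfig:
    """No direct exposure→outcome path and a strong mediated pathway.

    The exposure→mediator coefficients are tripled relative to the default
    so the indirect effect is large (log NIE ≈ 0.35): a fully mediated
    structure whose estimated proportion mediated is well separated from
    the direct-effect sampling noise.
    """
    cfg = _base_uncalibrated()
    mm = {name: replace(m, coef={**m.coef, "x": 3.0 * m.coef.get("x", 0.0)})
          for name, m in cfg.mediator_models.items()}
    om = replace(cfg.outcome_model, coef={**cfg.outcome_model.coef, "x": 0.0})
    return calibrate_config(replace(cfg, mediator_models=mm, outcome_model=om))


def unmediated_config() -> GeneratorConfig:
    """No exposure→mediator paths; direct exposure→outcome effect only."""
    cfg = _base_uncalibrated()
    mm = {name: replace(m, coef={**m.coef, "x": 0.0})
          for name, m in cfg.mediator_models.items()}
    om = replace(cfg.outcome_model, coef={**cfg.outcome_model.coef, "x": 0.20})
    return calibrate_config(replace(cfg, mediator_models=mm, outcome_model=om))


def rare_outcome_config(baseline: float = 0.04) -> GeneratorConfig:
    """Default structure with a rare outcome (marginal risk ``baseline``)."""
    cfg = _base_uncalibrated()
    targets = {**DEFAULT_TARGETS, "outcome": baseline}
    return calibrate_config(cfg, targets=targets)


def confounded_null_config() -> GeneratorConfig:
    """Strong confounding, zero causal exposure effect (direct or mediated)."""
    cfg = _base_uncalibrated()
    mm = {name: replace(m, coef={**m.coef, "x": 0.0})
          for name, m in cfg.mediator_models.items()}
    om = replace(cfg.outcome_model, coef={**cfg.outcome_model.coef, "x": 0.0})
    em = LogitModel(coef={"age_c": 0.06, "female": -0.30, "family_history": 0.80,
                          "comorbidity": 0.50, "poor_health": 1.00})
    return calibrate_config(replace(cfg, mediator_models=mm, outcome_model=om,
                                    exposure_model=em))


# ---------------------------------------------------------------------------
# IO

def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and not c.startswith("latent_")]
    if missing:
        raise ConfigError(f"cohort file missing required columns: {missing}")
    return df


def config_to_json(config: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=float)
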