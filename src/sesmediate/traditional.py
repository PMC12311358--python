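"""Difference and product-of-coefficients mediation, on the risk-ratio scale.

Both methods rest on three regressions sharing the same confounder set and
sample:

* total-effect model       E[Y | x, c]        -> exposure coefficient alpha_x
* mediator-adjusted model  E[Y | x, m, c]     -> exposure coefficient beta_x,
  mediator coefficients mu_j
* one mediator model per mediator  E[M_j | x, c] -> exposure effect gamma_j

The outcome models are fitted with a log link (modified Poisson), so
coefficients are log risk ratios and the multiplicative analogues are
TE = exp(alpha_x), NDE = exp(beta_x), NIE = exp(alpha_x - beta_x) for the
difference method.  For the product method the binary mediator models use a
logit link and the exposure effect entering each product is standardized to
the probability scale: gamma_j is the model-implied average marginal effect
of the exposure on P(M_j = 1) (risk difference), so that gamma_j * mu_j is a
log-risk-ratio contribution commensurate with the difference method.  The
total indirect effect is the sum of the per-mediator products, and
TE = exp(beta_x + sum_j gamma_j mu_j).

With identity links everywhere (``family="gaussian"``), both methods reduce
to the classical linear-model algebra and their indirect effects coincide
exactly; this equivalence is exercised in the test-suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import glm, prep
from .errors import EstimationError
from .mediation import EXPOSURE_COLUMN, _stratum_frame, analysis_confounders, proportion_mediated
from .simulate import MEDIATORS


def difference_fit(
    adf: pd.DataFrame,
    exposure_col: str,
    mediators=MEDIATORS,
    confounders=("age", "female", "family_history", "comorbidity", "poor_health"),
    family: str = "poisson",
) -> dict:
    """Difference-method decomposition on an analysis-format frame."""
    total = glm.fit_glm(adf, "y", [exposure_col] + list(confounders), family=family)
    adjusted = glm.fit_glm(
        adf, "y", [exposure_col] + list(mediators) + list(confounders),
        family=family, drop_degenerate=True,
    )
    alpha = float(total.params[exposure_col])
    beta = float(adjusted.params[exposure_col])
    out = {"alpha_x": alpha, "beta_x": beta, "indirect_sum": alpha - beta,
           "n": len(adf), "total_fit": total, "adjusted_fit": adjusted}
    if family == "poisson":
        te, nde, nie = np.exp(alpha), np.exp(beta), np.exp(alpha - beta)
        out.update(te=float(te), nde=float(nde), nie=float(nie),
                   pm=proportion_mediated(nie, te, nde))
    return out


def _marginal_exposure_effect(fit: glm.GLMResult, adf: pd.DataFrame,
                              exposure_col: str) -> float:
    """Average marginal effect of the exposure on the mediator's mean."""
    hi = adf.copy()
    hi[exposure_col] = 1.0
    lo = adf.copy()
    lo[exposure_col] = 0.0
    return float(np.mean(fit.predict(hi) - fit.predict(lo)))


def product_fit(
    adf: pd.DataFrame,
    exposure_col: str,
    mediators=MEDIATORS,
    confounders=("age", "female", "family_history", "comorbidity", "poor_health"),
    family: str = "poisson",
    mediator_family: str = "binomial",
) -> dict:
    """Product-of-coefficients decomposition on an analysis-format frame.

    Per-mediator indirect effect = (average marginal effect of exposure on
    the mediator) x (mediator's outcome coefficient); the total indirect is
    their sum — additivity over mediators is exact by construction.
    """
    adjusted = glm.fit_glm(
        adf, "y", [exposure_col] + list(mediators) + list(confounders),
        family=family, drop_degenerate=True,
    )
    beta = float(adjusted.params[exposure_col])
    per_mediator = {}
    for m in mediators:
        if m not in adjusted.params.index:
            per_mediator[m] = {"gamma_x": 0.0, "mu": 0.0, "indirect": 0.0}
            continue
        mfit = glm.fit_glm(adf, m, [exposure_col] + list(confounders),
                           family=mediator_family)
        gamma = (
            float(mfit.params[exposure_col]) if mediator_family == "gaussian"
            else _marginal_exposure_effect(mfit, adf, exposure_col)
        )
        mu = float(adjusted.params[m])
        per_mediator[m] = {"gamma_x": gamma, "mu": mu, "indirect": gamma * mu}
    indirect = float(sum(v["indirect"] for v in per_mediator.values()))
    total = beta + indirect
    out = {"beta_x": beta, "indirect_sum": indirect, "alpha_equiv": total,
           "per_mediator": per_mediator, "n": len(adf), "adjusted_fit": adjusted}
    if family == "poisson":
        te, nde, nie = np.exp(total), np.exp(beta), np.exp(indirect)
        out.update(te=float(te), nde=float(nde), nie=float(nie),
                   pm=proportion_mediated(nie, te, nde))
    return out


# ---------------------------------------------------------------------------
# full-pipeline point estimators (shared bootstrap signature)

def _prepare(raw: pd.DataFrame, exposure: str, stratum: str):
    sub = _stratum_frame(raw, stratum)
    adf = prep.dichotomize(sub, prep.alcohol_cutoffs(sub))
    return adf, EXPOSURE_COLUMN[exposure], analysis_confounders(exposure, stratum)


def difference_point(raw: pd.DataFrame, exposure: str = "education",
                     stratum: str = "all", **_ignored) -> dict:
    adf, xcol, conf = _prepare(raw, exposure, stratum)
    res = difference_fit(adf, xcol, MEDIATORS, conf)
    return {k: res[k] for k in ("te", "nde", "nie", "pm", "n")}


def product_point(raw: pd.DataFrame, exposure: str = "education",
                  stratum: str = "all", **_ignored) -> dict:
    adf, xcol, conf = _prepare(raw, exposure, stratum)
    res = product_fit(adf, xcol, MEDIATORS, conf)
    return {k: res[k] for k in ("te", "nde", "nie", "pm", "n")}


# ---------------------------------------------------------------------------
# progressively adjusted association models

def adjusted_association_models(raw: pd.DataFrame, exposure: str = "education",
                                strata=("all", "women", "men")) -> pd.DataFrame:
    """Three progressively adjusted risk-ratio models, overall and by sex.

    Model one adjusts for age and sex; model two adds comorbidity, family
    history and self-rated health (plus education when the exposure is
    occupational class); model three adds all seven mediators.  Wald
    intervals use the sandwich variance.
    """
    rows = []
    for stratum in strata:
        adf, xcol, conf2 = _prepare(raw, exposure, stratum)
        if len(np.unique(adf[xcol])) < 2:
            raise EstimationError(f"exposure {xcol} degenerate in stratum {stratum}")
        conf1 = ["age"] + (["female"] if stratum == "all" else [])
        model_terms = {
            "one": [xcol] + conf1,
            "two": [xcol] + conf2,
            "three": [xcol] + conf2 + list(MEDIATORS),
        }
        for name, terms in model_terms.items():
            fit = glm.fit_glm(adf, "y", terms, family="poisson", drop_degenerate=True)
            b = float(fit.params[xcol])
            se = float(fit.bse_robust()[xcol])
            rows.append({
                "exposure": exposure, "stratum": stratum, "model": name,
                "rr": float(np.exp(b)), "lo": float(np.exp(b - 1.959964 * se)),
                "hi": float(np.exp(b + 1.959964 * se)), "n": len(adf),
            })
    return pd.DataFrame(rows)
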