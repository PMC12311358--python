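"""Counterfactual decomposition of a total effect into natural direct and
indirect components, with all mediators taken jointly.

Three counterfactual mean risks identify the decomposition on the
risk-ratio scale:

* ``m_xx`` = E[Y(1, L(1), M(1))] — risk if everyone were exposed;
* ``m_ss`` = E[Y(0, L(0), M(0))] — risk if no one were exposed;
* ``m_xs`` = E[Y(1, L(0), M(0))] — the cross-world risk: exposed, but with
  the behavioural (L) and metabolic (M) mediators following their
  unexposed distribution.

Then TE = m_xx / m_ss, NDE = m_xs / m_ss, NIE = m_xx / m_xs, and
TE = NDE x NIE by construction.  The factual means come from a weighted
marginal structural model of the outcome on exposure alone; the cross-world
mean comes from a second weighted model with mediators, confounders and
exposure-mediator interactions, evaluated with exposure set to 1 over the
(weighted) empirical mediator-confounder distribution of the unexposed.

The proportion mediated is log(NIE) / log(TE) — the share of the total
log-risk-ratio transmitted through the mediators; an alternative on the
excess-relative-risk scale is available via ``scale="rr_minus_one"``.

Percentile bootstrap intervals re-run the entire pipeline per replicate:
tercile cut-offs, propensity model, weights, both outcome models and the
decomposition, so all estimation steps contribute uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import prep, weights as wmod
from .errors import EstimationError, InvalidRunError, SesmediateError
from .simulate import MEDIATORS

EXPOSURE_COLUMN = {"education": "x_edu", "occupation": "x_occ"}
STRATA = ("all", "women", "men")


@dataclass
class CounterfactualMeans:
    m_xx: float
    m_ss: float
    m_xs: float


@dataclass
class EffectDecomposition:
    """Point estimates and percentile bootstrap intervals for one cell."""

    method: str
    exposure: str
    stratum: str
    te_rr: float
    nde_rr: float
    nie_rr: float
    pm: float
    te_ci: tuple[float, float] | None = None
    nde_ci: tuple[float, float] | None = None
    nie_ci: tuple[float, float] | None = None
    pm_ci: tuple[float, float] | None = None
    n: int = 0
    bootstrap_B: int = 0
    bootstrap_seed: int | None = None
    bootstrap_failures: int = 0

    def to_dict(self) -> dict:
        d = {
            "method": self.method, "exposure": self.exposure, "stratum": self.stratum,
            "n": self.n, "te_rr": self.te_rr, "nde_rr": self.nde_rr,
            "nie_rr": self.nie_rr, "pm_pct": 100.0 * self.pm,
            "B": self.bootstrap_B, "seed": self.bootstrap_seed,
            "failures": self.bootstrap_failures,
        }
        for name, ci in [("te", self.te_ci), ("nde", self.nde_ci),
                         ("nie", self.nie_ci), ("pm", self.pm_ci)]:
            if ci is not None:
                scale = 100.0 if name == "pm" else 1.0
                d[f"{name}_lo"], d[f"{name}_hi"] = scale * ci[0], scale * ci[1]
        return d


@dataclass
class BootstrapResult:
    replicates: pd.DataFrame
    B: int
    seed: int
    n_failures: int
    failure_indices: list[int] = field(default_factory=list)

    def percentile_ci(self, column: str, level: float = 95.0) -> tuple[float, float]:
        a = (100.0 - level) / 2.0
        vals = self.replicates[column].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            return (float("nan"), float("nan"))
        lo, hi = np.percentile(vals, [a, 100.0 - a])
        return float(lo), float(hi)


# ---------------------------------------------------------------------------
# estimation of the three counterfactual means

def default_interactions(exposure_col: str, mediators=MEDIATORS) -> list[str]:
    """The full exposure x mediator product set."""
    return [f"{exposure_col}:{m}" for m in mediators]


def estimate_counterfactual_means(
    df: pd.DataFrame,
    ws: wmod.WeightSet,
    exposure_col: str,
    mediators: list[str] | tuple[str, ...] = MEDIATORS,
    confounders: list[str] | tuple[str, ...] = wmod.DEFAULT_CONFOUNDERS,
    interaction_terms: list[str] | None = None,
) -> CounterfactualMeans:
    """Estimate E[Y(1,L1,M1)], E[Y(0,L0,M0)] and the cross-world mean.

    The factual means are the weighted mean outcomes in each exposure group
    (identical to the predictions of a weighted saturated Poisson model of Y
    on exposure).  The cross-world mean standardizes the mediator-adjusted
    weighted model, evaluated at exposure 1, over the weighted empirical
    (L, M, c) distribution of the unexposed.
    """
    x = df[exposure_col].to_numpy(float)
    y = df["y"].to_numpy(float)
    w = ws.w
    exposed, unexposed = x == 1.0, x == 0.0
    if not unexposed.any() or not exposed.any():
        raise EstimationError("both exposure levels are required")
    m_xx = float(np.average(y[exposed], weights=w[exposed]))
    m_ss = float(np.average(y[unexposed], weights=w[unexposed]))

    terms = [exposure_col] + list(mediators) + list(confounders)
    if interaction_terms:
        terms = terms + list(interaction_terms)
    fit = wmod.weighted_poisson(df, "y", terms, weights=w, drop_degenerate=True)
    ref = df.loc[unexposed].copy()
    ref[exposure_col] = 1.0
    pred = fit.predict(ref)
    m_xs = float(np.average(pred, weights=w[unexposed]))
    return CounterfactualMeans(m_xx=m_xx, m_ss=m_ss, m_xs=m_xs)


def decompose(means: CounterfactualMeans) -> tuple[float, float, float]:
    """(TE, NDE, NIE) risk ratios from the three counterfactual means."""
    if min(means.m_xx, means.m_ss, means.m_xs) <= 0.0:
        raise EstimationError("counterfactual means must be positive to form ratios")
    te = means.m_xx / means.m_ss
    nde = means.m_xs / means.m_ss
    nie = means.m_xx / means.m_xs
    return te, nde, nie


def proportion_mediated(nie_rr: float, te_rr: float, nde_rr: float | None = None,
                        scale: str = "log") -> float:
    """Proportion mediated; NaN when the total effect is null.

    ``scale="log"`` (default) divides the indirect by the total effect on the
    log-risk-ratio scale.  ``scale="rr_minus_one"`` uses the excess relative
    risk: NDE (NIE - 1) / (TE - 1), which requires ``nde_rr``.
    """
    if scale == "log":
        lt = math.log(te_rr)
        if abs(lt) < 1e-12:
            return float("nan")
        return math.log(nie_rr) / lt
    if scale == "rr_minus_one":
        if nde_rr is None:
            raise ValueError("rr_minus_one scale requires nde_rr")
        if abs(te_rr - 1.0) < 1e-12:
            return float("nan")
        return nde_rr * (nie_rr - 1.0) / (te_rr - 1.0)
    raise ValueError(f"unknown proportion-mediated scale {scale!r}")


# ---------------------------------------------------------------------------
# full-pipeline point estimators (operate on the raw, post-exclusion cohort)

def _stratum_frame(raw: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return raw
    if stratum == "women":
        return raw[raw["sex"] == "female"]
    if stratum == "men":
        return raw[raw["sex"] == "male"]
    raise ValueError(f"unknown stratum {stratum!r}")


def analysis_confounders(exposure: str, stratum: str) -> list[str]:
    """Confounder set for a given exposure and stratum.

    Occupation analyses additionally adjust for low education; sex-stratified
    analyses drop the sex indicator.
    """
    conf = [c for c in wmod.DEFAULT_CONFOUNDERS if not (stratum != "all" and c == "female")]
    if exposure == "occupation":
        conf.append("x_edu")
    return conf


def counterfactual_point(
    raw: pd.DataFrame,
    exposure: str = "education",
    stratum: str = "all",
    interactions: str | list[str] | None = "xm",
    truncate: tuple[float, float] | None = None,
) -> dict:
    """Counterfactual TE/NDE/NIE/PM on one (possibly resampled) cohort.

    Re-estimates the alcohol terciles, the propensity model and both
    weighted outcome models from the records it is given, so it can serve
    directly as a bootstrap replicate estimator.
    """
    sub = _stratum_frame(raw, stratum)
    cutoffs = prep.alcohol_cutoffs(sub)
    adf = prep.dichotomize(sub, cutoffs)
    xcol = EXPOSURE_COLUMN[exposure]
    conf = analysis_confounders(exposure, stratum)
    ws = wmod.stabilized_weights(adf, xcol, conf, truncate=truncate)
    if interactions == "xm":
        inter = default_interactions(xcol)
    elif interactions is None:
        inter = []
    else:
        inter = list(interactions)
    means = estimate_counterfactual_means(
        adf, ws, xcol, MEDIATORS, conf, interaction_terms=inter
    )
    te, nde, nie = decompose(means)
    return {
        "te": te, "nde": nde, "nie": nie,
        "pm": proportion_mediated(nie, te, nde),
        "n": len(adf), "m_xx": means.m_xx, "m_ss": means.m_ss, "m_xs": means.m_xs,
        "weight_mean": ws.diagnostics["mean"],
    }


# ---------------------------------------------------------------------------
# bootstrap

def replicate_seed(master_seed: int, index: int) -> np.random.Generator:
    """Deterministic per-replicate stream; changing B leaves earlier
    replicates untouched."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(index)]))


def bootstrap_decomposition(
    raw: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], dict],
    B: int,
    seed: int,
    max_failure_rate: float = 0.05,
) -> BootstrapResult:
    """Resample individuals with replacement; re-run the estimator per replicate.

    Replicates raising an estimation error are logged and excluded; if more
    than ``max_failure_rate`` of them fail the whole run is invalid.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    n = len(raw)
    rows, failures = [], []
    for b in range(B):
        rng = replicate_seed(seed, b)
        idx = rng.integers(0, n, n)
        sample = raw.iloc[idx].reset_index(drop=True)
        try:
            rows.append(estimator(sample))
        except (SesmediateError, np.linalg.LinAlgError, FloatingPointError):
            failures.append(b)
    if len(failures) > max_failure_rate * B:
        raise InvalidRunError(
            f"{len(failures)}/{B} bootstrap replicates failed "
            f"(allowed {max_failure_rate:.0%})"
        )
    return BootstrapResult(
        replicates=pd.DataFrame(rows), B=B, seed=seed,
        n_failures=len(failures), failure_indices=failures,
    )


def decomposition_with_ci(
    raw: pd.DataFrame,
    method: str = "counterfactual",
    exposure: str = "education",
    stratum: str = "all",
    B: int = 1000,
    seed: int = 0,
    **options,
) -> EffectDecomposition:
    """Point estimates plus percentile bootstrap intervals for one grid cell."""
    from . import traditional  # local import; traditional shares this bootstrap

    estimators = {
        "counterfactual": counterfactual_point,
        "difference": traditional.difference_point,
        "product": traditional.product_point,
    }
    if method not in estimators:
        raise ValueError(f"unknown method {method!r}")
    est = estimators[method]

    def run(df):
        return est(df, exposure=exposure, stratum=stratum, **options)

    point = run(raw)
    boot = bootstrap_decomposition(raw, run, B=B, seed=seed)
    return EffectDecomposition(
        method=method, exposure=exposure, stratum=stratum,
        te_rr=point["te"], nde_rr=point["nde"], nie_rr=point["nie"], pm=point["pm"],
        te_ci=boot.percentile_ci("te"), nde_ci=boot.percentile_ci("nde"),
        nie_ci=boot.percentile_ci("nie"), pm_ci=boot.percentile_ci("pm"),
        n=point["n"], bootstrap_B=B, bootstrap_seed=seed,
        bootstrap_failures=boot.n_failures,
    )
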