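"""Stabilized inverse-probability-of-exposure weights and weighted risk models.

The weights reweight each exposure group to the marginal confounder
distribution: exposed records receive P(x=1) / P(x=1|c), unexposed ones
(1 - P(x=1)) / (1 - P(x=1|c)), with the conditional probability from a
logistic propensity model.  Stabilization keeps the mean weight near 1; the
mean is part of the diagnostics and is asserted in the test-suite on
well-specified simulations.

Risk models are "modified Poisson" fits: log-link Poisson score equations on
a binary outcome, with a sandwich covariance.  Reported confidence intervals
downstream come from the bootstrap; the robust covariance is still exposed
for single-fit summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm
from .errors import ConvergenceError, PositivityError

DEFAULT_CONFOUNDERS = ("age", "female", "family_history", "comorbidity", "poor_health")


@dataclass
class WeightSet:
    """Per-record stabilized weights plus diagnostics."""

    w: np.ndarray
    propensity: np.ndarray
    p_marginal: float
    exposure: str
    confounders: tuple[str, ...]
    truncation: tuple[float, float] | None = None

    @property
    def diagnostics(self) -> dict[str, float]:
        w = self.w
        return {
            "mean": float(w.mean()),
            "min": float(w.min()),
            "max": float(w.max()),
            "ess": float(w.sum() ** 2 / np.sum(w**2)),
        }


def stabilized_weights(
    df: pd.DataFrame,
    exposure: str,
    confounders: list[str] | tuple[str, ...] = DEFAULT_CONFOUNDERS,
    truncate: tuple[float, float] | None = None,
) -> WeightSet:
    """Estimate stabilized inverse-probability-of-exposure weights.

    ``truncate`` optionally clips the weights at the given percentile pair
    (e.g. ``(1, 99)``); the default applies no truncation.
    """
    x = df[exposure].to_numpy(float)
    if set(np.unique(x)) != {0.0, 1.0}:
        raise PositivityError(
            f"exposure {exposure!r} must take both values 0 and 1"
        )
    try:
        fit = glm.fit_glm(df, exposure, list(confounders), family="binomial")
    except ConvergenceError as err:
        # (quasi-)separation — a covariate pattern with a single exposure
        # level — drives the propensity MLE to 0/1 and IRLS never settles
        raise PositivityError(
            "propensity model did not converge; a covariate pattern with a "
            "single exposure level (positivity violation) is the usual cause"
        ) from err
    ps = fit.predict(df)
    # a degenerate covariate pattern (single exposure level) drives its
    # fitted propensity numerically to 0/1; no legitimate smooth fit gets
    # within 1e-8 of the boundary
    eps = 1e-8
    if np.any(ps <= eps) or np.any(ps >= 1 - eps):
        i = int(np.argmax((ps <= eps) | (ps >= 1 - eps)))
        pattern = {c: df[c].iloc[i] for c in confounders}
        raise PositivityError(
            f"propensity estimate of 0 or 1 for covariate pattern {pattern}"
        )
    p1 = float(x.mean())
    w = np.where(x == 1.0, p1 / ps, (1.0 - p1) / (1.0 - ps))
    if truncate is not None:
        lo, hi = np.percentile(w, truncate)
        w = np.clip(w, lo, hi)
    return WeightSet(
        w=w, propensity=ps, p_marginal=p1, exposure=exposure,
        confounders=tuple(confounders), truncation=truncate,
    )


def weighted_poisson(
    df: pd.DataFrame,
    outcome: str,
    terms: list[str],
    weights: np.ndarray | None = None,
    drop_degenerate: bool = False,
) -> glm.GLMResult:
    """Weighted modified-Poisson (log-link, robust-variance) risk model."""
    return glm.fit_glm(
        df, outcome, terms, family="poisson", weights=weights,
        drop_degenerate=drop_degenerate,
    )


def append_weights(df: pd.DataFrame, ws: WeightSet, column: str = "ipw") -> pd.DataFrame:
    """Return a copy of the cohort with the weight column attached."""
    out = df.copy()
    out[column] = ws.w
    return out
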