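"""Light-weight GLM fitting by iteratively reweighted least squares.

The mediation bootstrap re-estimates every model (propensity, marginal
structural, mediator, outcome) in each of B replicates, so the fitter is a
thin numpy IRLS loop rather than a full-featured modelling layer.  It covers
exactly the three canonical-link families the pipeline needs:

* ``poisson``  — log link; with a binary outcome this is the "modified
  Poisson" estimator of risk ratios (robust sandwich covariance).
* ``binomial`` — logit link, used for propensity scores and binary mediators.
* ``gaussian`` — identity link (ordinary weighted least squares), used for
  linear-system equivalence checks.

Coefficients and sandwich covariances are validated against statsmodels GLM
in the test-suite; statsmodels stays an independent cross-check rather than
the execution path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, RankDeficiencyError

_FAMILIES = ("poisson", "binomial", "gaussian")


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Resolve a term name to a column; ``a:b:...`` is an elementwise product."""
    parts = term.split(":")
    x = df[parts[0]].to_numpy(float)
    for p in parts[1:]:
        x = x * df[p].to_numpy(float)
    return x


def build_design(
    df: pd.DataFrame,
    terms: list[str],
    drop_degenerate: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Build an intercept-first design matrix from term names.

    A term is either a column of ``df`` or a product interaction written
    ``"a:b"``.  With ``drop_degenerate=True`` columns with zero variance are
    silently removed (needed inside bootstrap replicates where a rare
    mediator may vanish from a resample); otherwise they are reported as
    aliased.
    """
    cols = [np.ones(len(df))]
    names = ["const"]
    degenerate = []
    for term in terms:
        x = _term_column(df, term)
        if np.ptp(x) == 0.0:
            degenerate.append(term)
            continue
        cols.append(x)
        names.append(term)
    if degenerate and not drop_degenerate:
        raise RankDeficiencyError(degenerate)
    return np.column_stack(cols), names


@dataclass
class GLMResult:
    """A fitted GLM: coefficients, robust covariance, and a predictor."""

    params: pd.Series
    cov_robust: np.ndarray
    family: str
    terms: list[str]
    converged: bool
    n_iter: int
    deviance: float
    n_obs: int
    dropped_terms: list[str] = field(default_factory=list)

    def bse_robust(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.params.index)

    def linpred(self, df: pd.DataFrame) -> np.ndarray:
        # no degeneracy filtering here: prediction frames legitimately hold
        # covariates constant (e.g. exposure set to 1 for g-computation)
        eta = np.full(len(df), float(self.params["const"]))
        for term in self.terms:
            eta += float(self.params[term]) * _term_column(df, term)
        return eta

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Mean response at the covariate rows of ``df``."""
        eta = self.linpred(df)
        if self.family == "poisson":
            return np.exp(eta)
        if self.family == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def _mu(eta, family):
    if family == "poisson":
        return np.exp(np.clip(eta, -500, 30))
    if family == "binomial":
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    return eta


def _deviance(y, mu, w, family):
    if family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * np.sum(w * (term - (y - mu)))
    if family == "binomial":
        eps = 1e-12
        mu = np.clip(mu, eps, 1 - eps)
        return -2.0 * np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return np.sum(w * (y - mu) ** 2)


def fit_glm(
    df: pd.DataFrame,
    outcome: str,
    terms: list[str],
    family: str = "poisson",
    weights: np.ndarray | None = None,
    drop_degenerate: bool = False,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GLMResult:
    """Fit a canonical-link GLM by IRLS with a sandwich (HC0) covariance.

    ``weights`` are observation weights entering the estimating equations
    (e.g. stabilized inverse-probability weights); the sandwich covariance
    treats them as fixed.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    X, names = build_design(df, terms, drop_degenerate=drop_degenerate)
    kept_terms = [n for n in names if n != "const"]
    dropped = [t for t in terms if t not in kept_terms]
    y = df[outcome].to_numpy(float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,) or np.any(w < 0):
        raise ValueError("weights must be a nonnegative vector aligned to rows")

    # rank check up front so aliasing raises a named error, not a LinAlgError
    if np.linalg.matrix_rank(X) < p:
        r = np.linalg.qr(X, mode="r")
        aliased = [names[j] for j in range(p) if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise RankDeficiencyError(aliased or names)

    beta = np.zeros(p)
    ybar = np.average(y, weights=w) if w.sum() > 0 else y.mean()
    if family == "poisson":
        beta[0] = np.log(max(ybar, 1e-8))
    elif family == "binomial":
        ybar = min(max(ybar, 1e-8), 1 - 1e-8)
        beta[0] = np.log(ybar / (1 - ybar))
    else:
        beta[0] = ybar

    eta = X @ beta
    mu = _mu(eta, family)
    dev = _deviance(y, mu, w, family)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if family == "poisson":
            gprime = np.maximum(mu, 1e-12)           # d mu / d eta
            wk = np.maximum(w * mu, 1e-12)
            z = eta + (y - mu) / gprime
        elif family == "binomial":
            gprime = np.maximum(mu * (1 - mu), 1e-12)
            wk = np.maximum(w * gprime, 1e-12)
            z = eta + (y - mu) / gprime
        else:
            wk = np.maximum(w, 1e-12)
            z = y
        A = X.T @ (X * wk[:, None])
        b = X.T @ (wk * z)
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        # step-halving if the deviance worsens
        step = beta_new - beta
        for _ in range(25):
            eta_try = X @ (beta + step)
            mu_try = _mu(eta_try, family)
            dev_try = _deviance(y, mu_try, w, family)
            if np.isfinite(dev_try) and dev_try <= dev + 1e-10:
                break
            step *= 0.5
        delta = np.max(np.abs(step))
        beta = beta + step
        eta = X @ beta
        mu = _mu(eta, family)
        dev_old, dev = dev, _deviance(y, mu, w, family)
        trace.append(dev)
        # stop on coefficient stability or on a converged likelihood: a cell
        # with no events drives its coefficient to -inf while the deviance
        # (and every fitted mean) converges — the standard GLM stopping rule
        if (delta < tol or abs(dev - dev_old) < 1e-10 * (abs(dev) + 0.1)
                or (family == "gaussian" and it >= 1)):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations (family={family})",
            trace=trace,
        )

    if family == "poisson":
        wk = np.maximum(w * mu, 1e-12)
    elif family == "binomial":
        wk = np.maximum(w * mu * (1 - mu), 1e-12)
    else:
        wk = np.maximum(w, 1e-12)
    A = X.T @ (X * wk[:, None])
    bread = np.linalg.pinv(A)  # near-singular when a coefficient ran to -inf
    score = w * (y - mu)
    meat = (X * score[:, None]).T @ (X * score[:, None])
    cov = bread @ meat @ bread

    return GLMResult(
        params=pd.Series(beta, index=names),
        cov_robust=cov,
        family=family,
        terms=kept_terms,
        converged=converged,
        n_iter=it,
        deviance=float(dev),
        n_obs=n,
        dropped_terms=dropped,
    )
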