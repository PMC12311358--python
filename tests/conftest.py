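"""Shared fixtures: default synthetic cohort and an exactly enumerable toy.

The toy population has one binary confounder C, one binary mediator M and a
log-additive outcome risk, with all probabilities rational, so every record
pattern can be replicated with integer counts and every estimand has a
closed form.  It serves as the independent oracle for the counterfactual
means and the difference-method coefficients.
"""

import numpy as np
import pandas as pd
import pytest

from sesmediate import prep, simulate


@pytest.fixture(scope="session")
def default_cfg():
    return simulate.default_config()


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    return simulate.generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def kept_cohort(default_cohort):
    kept, _ = prep.apply_exclusions(default_cohort)
    return kept


@pytest.fixture(scope="session")
def analysis_frame(kept_cohort):
    return prep.dichotomize(kept_cohort, prep.alcohol_cutoffs(kept_cohort))


# --- exactly enumerable toy population -------------------------------------

P_C1 = 2 / 5
P_X_GIVEN_C = {0: 1 / 4, 1: 3 / 4}
P_M_GIVEN_X = {0: 1 / 5, 1: 1 / 2}
RISK_BASE, RISK_X, RISK_M, RISK_C = 1 / 20, 2.0, 3 / 2, 5 / 4


def toy_risk(x, m, c):
    return RISK_BASE * RISK_X**x * RISK_M**m * RISK_C**c


def make_toy_population() -> pd.DataFrame:
    """200 rows enumerating (c, x, m) with exact integer multiplicities.

    The outcome column carries the exact conditional risk rather than a
    Bernoulli draw; the log-link score equations are linear in y, so fits on
    this population reproduce population values exactly.
    """
    rows = []
    for c in (0, 1):
        for x in (0, 1):
            for m in (0, 1):
                p = (
                    (P_C1 if c else 1 - P_C1)
                    * (P_X_GIVEN_C[c] if x else 1 - P_X_GIVEN_C[c])
                    * (P_M_GIVEN_X[x] if m else 1 - P_M_GIVEN_X[x])
                )
                count = round(200 * p)
                assert abs(200 * p - count) < 1e-9
                rows.extend([{"c": c, "x": x, "m": m, "y": toy_risk(x, m, c)}] * count)
    return pd.DataFrame(rows)


def toy_truth() -> dict:
    """Closed-form counterfactual means and difference-method coefficients."""
    def mean_risk(x_set, mediator_law):
        pm = P_M_GIVEN_X[mediator_law]
        return sum(
            (P_C1 if c else 1 - P_C1)
            * ((1 - pm) * toy_risk(x_set, 0, c) + pm * toy_risk(x_set, 1, c))
            for c in (0, 1)
        )

    m_xx = mean_risk(1, 1)
    m_ss = mean_risk(0, 0)
    m_xs = mean_risk(1, 0)
    # E[Y|x,c] = exp(b0 + bx x + bc c) * (1 - p_m(x) + p_m(x) e^bm) is
    # log-additive because the mediator law ignores c, so alpha_x is exact:
    h = {x: 1 - P_M_GIVEN_X[x] + P_M_GIVEN_X[x] * RISK_M for x in (0, 1)}
    alpha_x = np.log(RISK_X) + np.log(h[1] / h[0])
    beta_x = np.log(RISK_X)
    return {
        "m_xx": m_xx, "m_ss": m_ss, "m_xs": m_xs,
        "te": m_xx / m_ss, "nde": m_xs / m_ss, "nie": m_xx / m_xs,
        "alpha_x": float(alpha_x), "beta_x": float(beta_x),
    }


@pytest.fixture(scope="session")
def toy():
    return make_toy_population(), toy_truth()
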