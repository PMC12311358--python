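"""E-values: sensitivity of risk-ratio estimates to unmeasured confounding.

The E-value of a risk ratio RR >= 1 is E = RR + sqrt(RR (RR - 1)): the
minimum strength of association, on the risk-ratio scale, that an
unmeasured confounder would need with both exposure and outcome to fully
explain the observed association.  Protective ratios are inverted before
evaluation, so evalue(r) = evalue(1/r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import EstimationError


def evalue(rr: float) -> float:
    """Point-estimate E-value; full precision (round only for display)."""
    if not rr > 0.0:
        raise EstimationError(f"risk ratio must be positive; got {rr}")
    r = rr if rr >= 1.0 else 1.0 / rr
    return r + math.sqrt(r * (r - 1.0))


@dataclass
class EvalueResult:
    rr: float
    rr_used: float
    evalue_point: float
    evalue_ci: float
    ci_crosses_null: bool


def evalue_ci(rr: float, lo: float, hi: float) -> EvalueResult:
    """E-values for a point estimate and the confidence limit closer to 1.

    A confidence interval containing 1 cannot be explained away by any
    further confounding, so its limit E-value is 1 and the crossing is
    flagged.
    """
    if not (lo <= rr <= hi):
        raise EstimationError(f"inconsistent interval: lo={lo}, rr={rr}, hi={hi}")
    point = evalue(rr)
    if lo <= 1.0 <= hi:
        return EvalueResult(rr, rr if rr >= 1 else 1 / rr, point, 1.0, True)
    limit = lo if rr >= 1.0 else hi  # the limit closer to the null
    return EvalueResult(rr, rr if rr >= 1 else 1 / rr, point, evalue(limit), False)


def evalue_table(decompositions) -> pd.DataFrame:
    """Batch E-values for a collection of EffectDecomposition results."""
    rows = []
    for d in decompositions:
        for effect, rr, ci in [("te", d.te_rr, d.te_ci), ("nde", d.nde_rr, d.nde_ci),
                               ("nie", d.nie_rr, d.nie_ci)]:
            if ci is None:
                res = EvalueResult(rr, rr if rr >= 1 else 1 / rr, evalue(rr),
                                   float("nan"), False)
            else:
                res = evalue_ci(rr, *ci)
            rows.append({
                "method": d.method, "exposure": d.exposure, "stratum": d.stratum,
                "effect": effect, "rr": rr,
                "evalue_point": round(res.evalue_point, 2),
                "evalue_ci_limit": round(res.evalue_ci, 2)
                if res.evalue_ci == res.evalue_ci else float("nan"),
                "ci_crosses_null": res.ci_crosses_null,
            })
    return pd.DataFrame(rows)
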