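"""Exclusion cascade, dichotomization rules and descriptive summaries.

The cohort arrives as one row per participant with raw measurements; this
module turns it into the analysis set: binary low-SES exposures, a
confounder vector, four behavioural and three metabolic binary mediators,
and the incident-outcome flag.

Cut-points:

* low education — basic education only (the middle category bundles
  vocational with upper secondary);
* low occupational class — unskilled and semiskilled manual workers;
* high alcohol — strictly above the sex-specific empirical tercile
  (2/3-quantile, linear interpolation) of consumption in cl/day;
* low physical activity — the two lowest of five self-rated levels;
* low fruit/vegetable intake — once per week or more seldom;
* obesity — BMI >= 30 kg/m2 (boundary inclusive);
* high fasting glucose — FPG >= 5.6 mmol/l;
* hypertension — SBP >= 140 or DBP >= 90 mmHg or antihypertensive use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError
from .simulate import (
    EXCLUSION_REASONS,
    FFQ_LEVELS,
    MEDIATORS,
    PA_LEVELS,
)

CONFOUNDERS = ("age", "female", "family_history", "comorbidity", "poor_health")
ANALYSIS_COLUMNS = (
    ["id", "x_edu", "x_occ"] + list(CONFOUNDERS) + list(MEDIATORS) + ["y"]
)

_LOW_PA_LEVELS = {"much_lower", "lower"}
_LOW_FFQ_LEVELS = {"never", "1_2_per_month", "1_per_week"}
_REQUIRED_RAW = [
    "age", "sex", "education_level", "occupational_class", "family_history",
    "comorbidity", "poor_health", "smoker_current", "alcohol_cl_day",
    "physical_activity", "fruitveg_freq", "bmi", "fpg", "sbp", "dbp",
    "antihypertensive_use", "incident_t2d",
]


@dataclass
class ExclusionTally:
    """Counts per exclusion reason in application order."""

    counts: dict[str, int]
    n_in: int
    n_out: int

    def conserved(self) -> bool:
        return self.n_in - sum(self.counts.values()) == self.n_out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "excluded": c} for r, c in self.counts.items()]
        rows.append({"reason": "retained", "excluded": self.n_out})
        return pd.DataFrame(rows)


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Remove flagged records in the stated order.

    A record matching several reasons is tallied only under the first
    matching reason, so the tally always sums to n_in - n_out.
    """
    n_in = len(df)
    remaining = np.ones(n_in, dtype=bool)
    counts = {}
    for reason in EXCLUSION_REASONS:
        flag = df[reason].to_numpy().astype(bool) if reason in df.columns else np.zeros(n_in, bool)
        hit = remaining & flag
        counts[reason] = int(hit.sum())
        remaining &= ~flag
    kept = df.loc[remaining].reset_index(drop=True)
    return kept, ExclusionTally(counts=counts, n_in=n_in, n_out=len(kept))


def alcohol_cutoffs(df: pd.DataFrame) -> dict[str, float]:
    """Sex-specific 2/3-quantiles of alcohol consumption (cl/day).

    "High" consumption downstream means strictly above the threshold, which
    keeps the high group at most one third of each sex stratum even under
    ties.
    """
    cutoffs = {}
    for sex, grp in df.groupby("sex"):
        vals = grp["alcohol_cl_day"].to_numpy(float)
        if len(vals) < 3:
            raise EstimationError(
                f"cannot estimate alcohol tercile for sex={sex!r}: "
                f"only {len(vals)} records"
            )
        cutoffs[sex] = float(np.quantile(vals, 2.0 / 3.0, method="linear"))
    return cutoffs


def dichotomize(df: pd.DataFrame, cutoffs: dict[str, float]) -> pd.DataFrame:
    """Map raw records to the analysis set (one row per retained participant)."""
    df = df.reset_index(drop=True)  # positional/index-aligned ops must agree
    for col in _REQUIRED_RAW:
        if col not in df.columns:
            raise EstimationError(f"missing required field '{col}'")
        if pd.isna(df[col]).any():
            raise EstimationError(f"missing values in required field '{col}'")
    bad_pa = set(df["physical_activity"]) - set(PA_LEVELS)
    if bad_pa:
        raise EstimationError(f"invalid physical_activity levels: {sorted(bad_pa)}")
    bad_fv = set(df["fruitveg_freq"]) - set(FFQ_LEVELS)
    if bad_fv:
        raise EstimationError(f"invalid fruitveg_freq levels: {sorted(bad_fv)}")
    missing_sex = set(df["sex"]) - set(cutoffs)
    if missing_sex:
        raise EstimationError(f"no alcohol cutoff for sex strata: {sorted(missing_sex)}")

    out = pd.DataFrame({"id": df["id"].to_numpy()})
    out["x_edu"] = (df["education_level"] == "basic").astype(int)
    out["x_occ"] = df["occupational_class"].isin(["unskilled", "semiskilled"]).astype(int)
    out["age"] = df["age"].to_numpy(float)
    out["female"] = (df["sex"] == "female").astype(int)
    for c in ("family_history", "comorbidity", "poor_health"):
        out[c] = df[c].astype(int).to_numpy()
    out["smoking"] = df["smoker_current"].astype(int).to_numpy()
    thr = df["sex"].map(cutoffs).to_numpy(float)
    out["high_alcohol"] = (df["alcohol_cl_day"].to_numpy(float) > thr).astype(int)
    out["low_physical_activity"] = df["physical_activity"].isin(_LOW_PA_LEVELS).astype(int)
    out["low_fruitveg"] = df["fruitveg_freq"].isin(_LOW_FFQ_LEVELS).astype(int)
    out["obesity"] = (df["bmi"].to_numpy(float) >= 30.0).astype(int)
    out["high_fpg"] = (df["fpg"].to_numpy(float) >= 5.6).astype(int)
    out["hypertension"] = (
        (df["sbp"].to_numpy(float) >= 140.0)
        | (df["dbp"].to_numpy(float) >= 90.0)
        | df["antihypertensive_use"].astype(bool).to_numpy()
    ).astype(int)
    out["y"] = df["incident_t2d"].astype(int).to_numpy()
    return out[ANALYSIS_COLUMNS]


def prepare(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Exclusions, tercile estimation and dichotomization in one call."""
    kept, tally = apply_exclusions(raw)
    cutoffs = alcohol_cutoffs(kept)
    return dichotomize(kept, cutoffs), tally


_BINARY_ROWS = [
    ("female", "women"), ("family_history", "family_history"),
    ("comorbidity", "comorbidity"), ("poor_health", "poor_health"),
    ("smoking", "smoking"), ("high_alcohol", "high_alcohol"),
    ("low_physical_activity", "low_physical_activity"),
    ("low_fruitveg", "low_fruitveg"), ("obesity", "obesity"),
    ("high_fpg", "high_fpg"), ("hypertension", "hypertension"),
    ("y", "incident_t2d"),
]
_CONTINUOUS_RAW_ROWS = [("bmi", "bmi"), ("fpg", "fpg"), ("sbp", "sbp"), ("dbp", "dbp")]


def describe(analysis: pd.DataFrame, group_by: str = "x_edu",
             raw: pd.DataFrame | None = None) -> pd.DataFrame:
    """Descriptive table: mean (SD) for continuous, n (%) for binary variables.

    Emitted overall and within each exposure group.  When the raw cohort is
    supplied (joined on ``id``) the continuous measurements behind the
    metabolic mediators are summarized too.
    """
    if analysis.empty:
        raise EstimationError("describe requires a nonempty analysis set")
    frame = analysis
    if raw is not None:
        frame = analysis.merge(
            raw[["id"] + [c for c, _ in _CONTINUOUS_RAW_ROWS]], on="id", how="left"
        )
    groups = {"total": frame}
    for level in (0, 1):
        groups[f"{group_by}={level}"] = frame[frame[group_by] == level]

    rows = []
    cont = [("age", "age")] + (_CONTINUOUS_RAW_ROWS if raw is not None else [])
    for col, label in cont:
        row = {"variable": label, "kind": "continuous"}
        for gname, g in groups.items():
            vals = g[col].to_numpy(float)
            row[f"{gname}_mean"] = float(np.mean(vals)) if len(vals) else float("nan")
            row[f"{gname}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(row)
    for col, label in _BINARY_ROWS:
        row = {"variable": label, "kind": "binary"}
        for gname, g in groups.items():
            n = int(g[col].sum()) if len(g) else 0
            row[f"{gname}_n"] = n
            row[f"{gname}_pct"] = 100.0 * n / len(g) if len(g) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
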