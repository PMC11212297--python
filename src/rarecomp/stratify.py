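"""Risk stratification by comorbidity level and E-value sensitivity analysis.

Comorbidity gradings (such as CMG comorbidity levels 0-4) are themselves
derived from coded diagnoses, including some of the adverse events under
study, so adjusting for them inside the outcome model would build the
outcome into a predictor.  Instead, the analysis is *stratified*: it runs
in parallel on nested subsets, subset(k) holding all visits with
comorbidity level <= k, so subset(4) is the full cohort.

E-values quantify robustness to unmeasured confounding: the E-value of a
risk ratio RR >= 1 is

    E = RR + sqrt(RR * (RR - 1)),

the minimum strength of association (on the risk-ratio scale) an
unmeasured confounder must have with both arm and outcome to explain the
observed association away.  For RR < 1 the formula is applied to 1/RR.
With rare outcomes (all adverse-event proportions here are below a few
percent) the adjusted odds ratio approximates the risk ratio and is used
directly; for common outcomes a square-root conversion
RR ~ sqrt(OR) is available.  The confidence-interval E-value uses the CI
limit closer to the null and equals 1 when the CI crosses 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "StratumProfile",
    "EValueResult",
    "cumulative_strata",
    "stratum_profile",
    "e_value",
    "proportions_table",
]

logger = logging.getLogger(__name__)

CL_COLUMN = "comorbidity_level"
ARM_COLUMN = "arm"
EVENT_COLUMN = "event"


def cumulative_strata(cohort: pd.DataFrame) -> dict:
    """Nested risk strata: {k: rows with comorbidity_level <= k} for k = 0..4."""
    if CL_COLUMN not in cohort.columns:
        raise ValueError(f"cohort is missing the {CL_COLUMN!r} column")
    cl = cohort[CL_COLUMN]
    bad = cohort.index[(cl < 0) | (cl > 4) | cl.isna()]
    if len(bad):
        raise ValueError(f"comorbidity_level outside 0..4 at rows {list(bad[:10])}")
    return {k: cohort[cl <= k] for k in range(5)}


@dataclass
class StratumProfile:
    """Per-arm descriptive statistics of one risk stratum."""

    cl_max: int
    n_total: int
    n_rural: int
    rural_fraction: float
    p_event_rural: float
    p_event_referral: float
    covariate_stats: dict = field(default_factory=dict)   # name -> {arm: {...}}
    event_proportions: dict = field(default_factory=dict)  # event name -> {arm: prop}
    missing_arms: tuple = ()

    def to_dict(self) -> dict:
        return {
            "cl_max": self.cl_max,
            "n_total": self.n_total,
            "n_rural": self.n_rural,
            "rural_fraction": self.rural_fraction,
            "p_event_rural": self.p_event_rural,
            "p_event_referral": self.p_event_referral,
            "covariates": self.covariate_stats,
            "event_proportions": self.event_proportions,
            "missing_arms": list(self.missing_arms),
        }


def stratum_profile(subset: pd.DataFrame, covariates=(), cl_max: int | None = None,
                    event_columns=()) -> StratumProfile:
    """Exact sample statistics per arm for one stratum.

    Continuous covariates get mean/sd per arm, binary ones a proportion.
    ``event_columns`` names individual adverse-event indicator columns to
    tabulate per arm alongside the combined ``event``.  An arm absent from
    the subset is flagged and its statistics reported as NaN.
    """
    if subset.empty:
        raise ValueError("empty stratum")
    arms = ("rural", "referral")
    present = {a for a in arms if (subset[ARM_COLUMN] == a).any()}
    missing = tuple(a for a in arms if a not in present)
    if missing:
        logger.warning("stratum has no %s visits; partial profile", "/".join(missing))
    by_arm = {a: subset[subset[ARM_COLUMN] == a] for a in arms}

    def event_p(arm):
        d = by_arm[arm]
        return float(d[EVENT_COLUMN].mean()) if len(d) else float("nan")

    cov_stats: dict = {}
    for name in covariates:
        vals = subset[name]
        binary = set(pd.unique(vals.dropna())) <= {0, 1, 0.0, 1.0}
        cov_stats[name] = {}
        for a in arms:
            v = by_arm[a][name]
            if not len(v):
                cov_stats[name][a] = {"n": 0}
            elif binary:
                cov_stats[name][a] = {"n": int(len(v)), "proportion": float(v.mean())}
            else:
                cov_stats[name][a] = {
                    "n": int(len(v)), "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                }

    event_props = {
        ev: {a: (float(by_arm[a][ev].mean()) if len(by_arm[a]) else float("nan")) for a in arms}
        for ev in event_columns
    }
    n_rural = int(len(by_arm["rural"]))
    return StratumProfile(
        cl_max=int(subset[CL_COLUMN].max()) if cl_max is None else cl_max,
        n_total=int(len(subset)),
        n_rural=n_rural,
        rural_fraction=n_rural / len(subset),
        p_event_rural=event_p("rural"),
        p_event_referral=event_p("referral"),
        covariate_stats=cov_stats,
        event_proportions=event_props,
        missing_arms=missing,
    )


def proportions_table(cohort: pd.DataFrame, covariates=(), event_columns=()) -> pd.DataFrame:
    """Descriptive table across the five cumulative strata (one row per stratum)."""
    rows = []
    for k, subset in cumulative_strata(cohort).items():
        if subset.empty:
            continue
        prof = stratum_profile(subset, covariates, cl_max=k, event_columns=event_columns)
        rows.append(
            {
                "cl_max": k,
                "n_total": prof.n_total,
                "n_rural": prof.n_rural,
                "rural_fraction": prof.rural_fraction,
                "p_event_rural": prof.p_event_rural,
                "p_event_referral": prof.p_event_referral,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EValueResult:
    """E-values for an odds-ratio point estimate and its CI limit closer to 1."""

    or_point: float
    or_ci_limit: float
    e_value_point: float
    e_value_ci: float

    def to_dict(self) -> dict:
        return {
            "or_point": self.or_point,
            "or_ci_limit": self.or_ci_limit,
            "e_value_point": self.e_value_point,
            "e_value_ci": self.e_value_ci,
        }


def _e_from_rr(rr: float) -> float:
    if rr < 1.0:
        rr = 1.0 / rr
    return rr + math.sqrt(rr * (rr - 1.0))


def _or_to_rr(or_value: float, rare_outcome: bool) -> float:
    # Rare outcomes: OR ~ RR.  Common outcomes: RR ~ sqrt(OR) (the usual
    # approximate conversion for E-value computation).
    return or_value if rare_outcome else math.sqrt(or_value)


def e_value(or_point: float, ci_lo: float, ci_hi: float,
            rare_outcome: bool = True) -> EValueResult:
    """E-value sensitivity analysis for an adjusted odds ratio and its 95% CI.

    Returns the point-estimate E-value and the CI E-value (computed from
    the limit closer to the null; 1 when the interval includes 1).
    """
    if not (or_point > 0 and ci_lo > 0 and ci_hi > 0):
        raise ValueError("odds ratios and CI limits must be positive")
    if not ci_lo <= or_point <= ci_hi:
        raise ValueError("need ci_lo <= or_point <= ci_hi")
    e_point = _e_from_rr(_or_to_rr(or_point, rare_outcome))
    if ci_lo <= 1.0 <= ci_hi:
        e_ci = 1.0
        limit = 1.0
    else:
        limit = ci_lo if ci_lo > 1.0 else ci_hi  # limit closer to the null
        e_ci = _e_from_rr(_or_to_rr(limit, rare_outcome))
    return EValueResult(
        or_point=or_point, or_ci_limit=limit,
        e_value_point=e_point, e_value_ci=e_ci,
    )
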