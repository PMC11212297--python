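"""Noninferiority margins and one-sided tests for rare adverse-event rates.

A superiority test of H0: tau_t = tau_c cannot show that a treatment arm
(e.g. rural facilities) is *as safe as* the control (referral facilities);
failing to reject is not evidence of equivalence.  The noninferiority
formulation tests

    H0: tau_t - tau_c >= delta    vs    H1: tau_t - tau_c < delta,

where delta > 0 is the largest clinically tolerable excess in the
treatment arm's adverse-event proportion.  Rejecting H0 is evidence that
the treatment arm is noninferior.

Margin rule.  A conservative margin is half the 95% confidence-interval
half-width (the "margin of error") of the observed control-minus-treatment
difference: for a reported difference of 0.3% +/- 0.1%, delta = 0.05%.

The proportion-scale margin is carried onto the log-odds scale through the
control proportion: delta corresponds to the odds ratio obtained by
lifting the control event proportion from tau_c to tau_c + delta.  A
margin on the treatment coefficient of a logistic model then supports
noninferiority tests on *adjusted* odds ratios, with a one-sided Wald test
for the maximum-likelihood engine and a one-sided penalized likelihood
ratio test for the Firth engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .firth import DesignSpec, fit_logistic, penalized_lrt, wald_test

__all__ = [
    "Margin",
    "NoninferiorityResult",
    "margin_from_ci",
    "margin_to_log_or",
    "test_proportions_ni",
    "test_or_ni",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.025  # one-sided, the clinical-trial convention


@dataclass(frozen=True)
class Margin:
    """A noninferiority margin on both the proportion and log-odds scales."""

    delta_prop: float
    tau_c: float
    delta_log_or: float
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        if self.delta_prop < 0:
            raise ValueError("delta_prop must be >= 0")
        if not 0.0 < self.tau_c < 1.0:
            raise ValueError("tau_c must lie strictly in (0, 1)")

    @property
    def degenerate(self) -> bool:
        """A zero margin collapses noninferiority to one-sided superiority."""
        return self.delta_prop == 0.0


@dataclass(frozen=True)
class NoninferiorityResult:
    margin: Margin
    scale: str               # "proportion" or "log-odds-ratio"
    statistic: float
    p_value: float
    alpha: float
    noninferior_at_alpha: bool
    engine: str = "proportions"
    estimate: float = float("nan")

    def report(self) -> str:
        lines = [
            f"Noninferiority test ({self.scale} scale, engine={self.engine})",
            f"  margin: delta = {self.margin.delta_prop:.6g} (proportion scale, "
            f"{self.margin.provenance}); {self.margin.delta_log_or:.6g} (log-OR scale)",
            f"  H0: excess >= delta   H1: excess < delta",
            f"  statistic = {self.statistic:.4f}, one-sided p = {self.p_value:.4g}",
            f"  conclusion at alpha={self.alpha:g}: "
            + ("noninferior" if self.noninferior_at_alpha else "noninferiority not shown"),
        ]
        if self.margin.degenerate:
            lines.append("  note: delta = 0 -- this is a one-sided superiority test")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "engine": self.engine,
            "delta_prop": self.margin.delta_prop,
            "delta_log_or": self.margin.delta_log_or,
            "margin_provenance": self.margin.provenance,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "noninferior_at_alpha": bool(self.noninferior_at_alpha),
            "estimate": self.estimate,
        }


def margin_to_log_or(tau_c: float, delta_prop: float) -> float:
    """Log odds ratio of lifting the control proportion by ``delta_prop``.

    Returns log[ ((tau_c + d) / (1 - tau_c - d)) / (tau_c / (1 - tau_c)) ].
    """
    if not 0.0 < tau_c < 1.0:
        raise ValueError("tau_c must lie strictly in (0, 1)")
    if tau_c + delta_prop >= 1.0:
        raise ValueError("tau_c + delta_prop must be < 1")
    odds_shifted = (tau_c + delta_prop) / (1.0 - tau_c - delta_prop)
    odds_c = tau_c / (1.0 - tau_c)
    return math.log(odds_shifted / odds_c)


def margin_from_ci(tau_t: float, tau_c: float, n_t: int, n_c: int,
                   margin_of_error: float | None = None) -> Margin:
    """Select delta = half the 95% margin of error of the difference in proportions.

    The Wald 95% half-width is m = 1.96 * sqrt(tau_t q_t / n_t + tau_c q_c / n_c)
    and delta = m / 2.  When a study reports the margin of error directly
    (the "+/-" of a difference), pass it as ``margin_of_error`` and the
    sample sizes are not used.
    """
    for p, lab in ((tau_t, "tau_t"), (tau_c, "tau_c")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{lab} must lie in [0, 1]")
    if margin_of_error is None:
        if n_t <= 0 or n_c <= 0:
            raise ValueError("sample sizes must be positive")
        margin_of_error = 1.96 * math.sqrt(
            tau_t * (1.0 - tau_t) / n_t + tau_c * (1.0 - tau_c) / n_c
        )
    if margin_of_error < 0:
        raise ValueError("margin of error must be >= 0")
    delta = margin_of_error / 2.0
    if delta == 0.0:
        logger.warning("degenerate margin: delta = 0 (both proportions carry no variance)")
    return Margin(
        delta_prop=delta,
        tau_c=tau_c,
        delta_log_or=margin_to_log_or(tau_c, delta),
        provenance="half-ci-rule",
    )


def test_proportions_ni(events_t: int, n_t: int, events_c: int, n_c: int,
                        margin: Margin, alpha: float = DEFAULT_ALPHA) -> NoninferiorityResult:
    """One-sided Wald z-test of H0: tau_t - tau_c >= delta on raw proportions.

    z = (p_t - p_c - delta) / sqrt(p_t q_t / n_t + p_c q_c / n_c); small
    (negative) z favors noninferiority.  With delta = 0 this is exactly the
    ordinary one-sided superiority test.
    """
    if not (0 <= events_t <= n_t and 0 <= events_c <= n_c):
        raise ValueError("event counts must lie in [0, n]")
    p_t = events_t / n_t
    p_c = events_c / n_c
    var = p_t * (1.0 - p_t) / n_t + p_c * (1.0 - p_c) / n_c
    if var == 0.0:
        raise ValueError("zero variance: both arms are degenerate (all or no events)")
    z = (p_t - p_c - margin.delta_prop) / math.sqrt(var)
    p_value = float(stats.norm.cdf(z))
    if margin.degenerate:
        logger.warning("delta = 0: noninferiority test collapses to one-sided superiority")
    return NoninferiorityResult(
        margin=margin,
        scale="proportion",
        statistic=z,
        p_value=p_value,
        alpha=alpha,
        noninferior_at_alpha=p_value < alpha,
        engine="proportions",
        estimate=p_t - p_c,
    )


def test_or_ni(cohort, design: DesignSpec, margin: Margin, engine: str = "firth",
               alpha: float = DEFAULT_ALPHA) -> NoninferiorityResult:
    """Noninferiority test on the adjusted (log) odds ratio of the treatment arm.

    Tests H0: beta_treatment >= delta_log_or against H1: beta < delta_log_or.
    The Firth engine uses the one-sided penalized likelihood ratio test at
    the shifted null; the maximum-likelihood engine uses a one-sided Wald
    test, which suffices away from separation.
    """
    if margin.degenerate:
        logger.warning("delta = 0: noninferiority on the odds ratio collapses to superiority")
    null = margin.delta_log_or
    if engine == "firth":
        test = penalized_lrt(cohort, design, design.treatment, null_value=null, sided="less")
    elif engine == "mle":
        fit = fit_logistic(cohort, design)
        test = wald_test(fit, design.treatment, null_value=null, sided="less")
    else:
        raise ValueError(f"engine must be 'firth' or 'mle', got {engine!r}")
    return NoninferiorityResult(
        margin=margin,
        scale="log-odds-ratio",
        statistic=test.statistic,
        p_value=test.p_value,
        alpha=alpha,
        noninferior_at_alpha=test.p_value < alpha,
        engine=engine,
        estimate=test.estimate,
    )
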