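"""Monte Carlo power analysis for the facility-effect test.

For a scenario (per-arm adverse-event proportions, rural fraction, null
covariates) and a total sample size n, power is estimated by simulation:
each replication draws a cohort, fits the event ~ arm + covariates model
with the chosen engine, and tests the arm coefficient against zero --
two-sided Wald for the maximum-likelihood engine, two-sided penalized
likelihood ratio test for the Firth engine.  Power is the fraction of
replications with p < alpha.  Replications whose maximum-likelihood fit
fails (single-class outcome, separation, non-convergence) are counted as
non-significant and reported in ``failed_fits``; discarding them would
bias power upward.

Both engines are evaluated on *identical* simulated cohorts: replication
seeds are derived from the root seed independently of the engine, so
engine comparisons are paired.

:func:`min_sample_size` searches a [grid_lo, grid_hi] range for the
smallest n reaching a target power, using a doubling coarse grid followed
by bisection to a fixed resolution, under a monotone-power assumption
(violations beyond Monte Carlo noise are warned about).  Scenarios whose
power at grid_hi falls short return an "above-grid" sentinel.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ScenarioPreset, _simulate_arrays
from .firth import INTERCEPT, SeparationError, _fit_core, _plrt_core

__all__ = [
    "PowerEstimate",
    "MinNResult",
    "estimate_power",
    "min_sample_size",
    "run_power_table",
]

logger = logging.getLogger(__name__)

TREATMENT = "arm"
DEFAULT_REPLICATIONS = 1000
DEFAULT_ALPHA = 0.05
GRID_LO, GRID_HI, RESOLUTION = 1000, 100_000, 10


@dataclass(frozen=True)
class PowerEstimate:
    """Monte Carlo power with its binomial standard error."""

    engine: str
    n: int
    replications: int
    power: float
    alpha: float
    failed_fits: int = 0

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.power * (1.0 - self.power) / self.replications)

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "n": self.n,
            "replications": self.replications,
            "power": self.power,
            "mc_se": self.mc_se,
            "alpha": self.alpha,
            "failed_fits": self.failed_fits,
        }


@dataclass(frozen=True)
class MinNResult:
    """Smallest n on the search grid reaching the target power."""

    engine: str
    target_power: float
    n_min: int | None           # None when power at grid_hi < target
    grid_lo: int
    grid_hi: int
    resolution: int

    @property
    def above_grid(self) -> bool:
        return self.n_min is None

    @property
    def label(self) -> str:
        return f">{self.grid_hi}" if self.above_grid else str(self.n_min)

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "target_power": self.target_power,
            "n_min": self.n_min,
            "label": self.label,
            "grid_lo": self.grid_lo,
            "grid_hi": self.grid_hi,
            "resolution": self.resolution,
        }


def _rep_pvalues(preset: ScenarioPreset, n: int, replications: int, seed,
                 do_mle: bool, do_firth: bool, alpha: float):
    """Simulate ``replications`` cohorts; return per-engine rejection counts.

    The per-replication seed stream depends only on (seed, replication),
    never on the engine, so both engines see the same cohorts.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    children = np.random.SeedSequence(seed).spawn(replications)
    names = None
    rej = {"mle": 0, "firth": 0}
    failed = {"mle": 0, "firth": 0}
    for child in children:
        rng = np.random.default_rng(child)
        y, arm01, C, cov_names = _simulate_arrays(preset, n, rng)
        if names is None:
            names = [INTERCEPT, TREATMENT, *cov_names]
        X = np.column_stack([np.ones(len(y)), arm01, C])
        if do_firth:
            try:
                fit = _fit_core(y, X, names, engine="firth", check=False)
                tr = _plrt_core(y, X, names, TREATMENT, 0.0, "two-sided", full_fit=fit)
                if tr.p_value < alpha:
                    rej["firth"] += 1
            except (RuntimeError, np.linalg.LinAlgError, ValueError):
                failed["firth"] += 1
        if do_mle:
            try:
                fit = _fit_core(y, X, names, engine="mle", check=False)
                if not fit.converged or fit.separation_flag:
                    failed["mle"] += 1
                else:
                    j = names.index(TREATMENT)
                    se = fit.bse.iloc[j]
                    if not se > 0:
                        failed["mle"] += 1
                    else:
                        z = fit.params.iloc[j] / se
                        from scipy.stats import norm

                        if 2.0 * norm.sf(abs(z)) < alpha:
                            rej["mle"] += 1
            except (SeparationError, RuntimeError, np.linalg.LinAlgError, ValueError):
                failed["mle"] += 1
    return rej, failed


def estimate_power(preset: ScenarioPreset, n: int | None = None, engine: str = "firth",
                   replications: int = DEFAULT_REPLICATIONS, alpha: float = DEFAULT_ALPHA,
                   seed: int = 0) -> PowerEstimate:
    """Monte Carlo power of the facility-effect test at total sample size n.

    ``n`` defaults to the preset's available sample size.  With equal arm
    event proportions the estimate measures the test's type-I error and
    should sit near ``alpha``.
    """
    if engine not in ("mle", "firth"):
        raise ValueError(f"engine must be 'mle' or 'firth', got {engine!r}")
    if n is None:
        n = preset.n_total
    if preset.p_event_rural == 0.0 and preset.p_event_referral == 0.0:
        logger.warning("degenerate preset: both event proportions are 0; power is 0")
        return PowerEstimate(engine, n, replications, 0.0, alpha, failed_fits=replications)
    rej, failed = _rep_pvalues(
        preset, n, replications, seed, do_mle=engine == "mle",
        do_firth=engine == "firth", alpha=alpha,
    )
    return PowerEstimate(
        engine=engine, n=n, replications=replications,
        power=rej[engine] / replications, alpha=alpha, failed_fits=failed[engine],
    )


def _estimate_power_paired(preset, n, replications, alpha, seed):
    """Both engines on the same simulated cohorts; returns (mle, firth) estimates."""
    rej, failed = _rep_pvalues(preset, n, replications, seed, True, True, alpha)
    return tuple(
        PowerEstimate(eng, n, replications, rej[eng] / replications, alpha, failed[eng])
        for eng in ("mle", "firth")
    )


def _point_seed(seed: int, n: int) -> int:
    # order-independent per-grid-point seed so bisection paths do not matter
    return int(np.random.SeedSequence((seed, n)).generate_state(1)[0] % (2**31))


def _round_to(n: float, resolution: int) -> int:
    return int(round(n / resolution)) * resolution


def min_sample_size(preset: ScenarioPreset, engine: str = "firth", target_power: float = 0.8,
                    grid_lo: int = GRID_LO, grid_hi: int = GRID_HI,
                    resolution: int = RESOLUTION, replications: int = 300,
                    alpha: float = DEFAULT_ALPHA, seed: int = 0) -> MinNResult:
    """Smallest n in [grid_lo, grid_hi] with estimated power >= target_power.

    Doubling coarse grid from grid_lo, then bisection between the
    bracketing pair down to ``resolution``.  Assumes power is monotone
    nondecreasing in n; coarse-grid decreases beyond 3 pooled Monte Carlo
    standard errors trigger a warning.  Returns the above-grid sentinel
    when even n = grid_hi falls short of the target.
    """
    if not grid_lo < grid_hi:
        raise ValueError("need grid_lo < grid_hi")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")

    def power_at(n: int) -> float:
        est = estimate_power(preset, n, engine, replications, alpha, _point_seed(seed, n))
        logger.info("min-n search %s %s: n=%d power=%.3f", preset.label, engine, n, est.power)
        return est.power

    # doubling coarse grid
    coarse: list[tuple[int, float]] = []
    n = grid_lo
    bracket = None
    while True:
        p = power_at(n)
        if coarse:
            prev_n, prev_p = coarse[-1]
            pooled_se = math.sqrt((p * (1 - p) + prev_p * (1 - prev_p)) / replications)
            if p < prev_p - 3.0 * pooled_se:
                logger.warning(
                    "power not monotone beyond MC noise: %.3f at n=%d vs %.3f at n=%d",
                    prev_p, prev_n, p, n,
                )
        coarse.append((n, p))
        if p >= target_power:
            bracket = (coarse[-2][0] if len(coarse) > 1 else grid_lo, n)
            break
        if n >= grid_hi:
            break
        n = min(n * 2, grid_hi)

    if bracket is None:
        return MinNResult(engine, target_power, None, grid_lo, grid_hi, resolution)
    lo, hi = bracket
    if hi == grid_lo:
        return MinNResult(engine, target_power, grid_lo, grid_lo, grid_hi, resolution)
    while hi - lo > resolution:
        mid = _round_to((lo + hi) / 2.0, resolution)
        if mid <= lo or mid >= hi:
            break
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return MinNResult(engine, target_power, hi, grid_lo, grid_hi, resolution)


def run_power_table(presets, replications: int = DEFAULT_REPLICATIONS,
                    alpha: float = DEFAULT_ALPHA, seed: int = 0,
                    include_min_n: bool = True, min_n_replications: int = 300,
                    target_power: float = 0.8, grid_lo: int = GRID_LO,
                    grid_hi: int = GRID_HI, resolution: int = RESOLUTION) -> pd.DataFrame:
    """Power summary across scenarios: one row per preset, both engines.

    Columns report the scenario description, available-n power for the
    maximum-likelihood and Firth engines (paired on identical cohorts) and,
    when ``include_min_n`` is set, the minimum n reaching ``target_power``
    for each engine (the sentinel rendered as ">grid_hi").
    """
    rows = []
    for idx, preset in enumerate(presets):
        t0 = time.perf_counter()
        row_seed = int(
            np.random.SeedSequence((seed, idx, preset.cl_max, preset.n_total))
            .generate_state(1)[0] % (2**31)
        )
        est_mle, est_firth = _estimate_power_paired(
            preset, preset.n_total, replications, alpha, row_seed,
        )
        row = {
            "procedure": preset.procedure,
            "cl_max": preset.cl_max,
            "n_total": preset.n_total,
            "n_rural": preset.n_rural,
            "rural_fraction": preset.rural_fraction,
            "p_event_rural": preset.p_event_rural,
            "p_event_referral": preset.p_event_referral,
            "power_mle": est_mle.power,
            "power_firth": est_firth.power,
            "mc_se_mle": est_mle.mc_se,
            "mc_se_firth": est_firth.mc_se,
            "failed_fits_mle": est_mle.failed_fits,
        }
        if include_min_n:
            for eng in ("mle", "firth"):
                res = min_sample_size(
                    preset, eng, target_power, grid_lo, grid_hi, resolution,
                    min_n_replications, alpha, seed,
                )
                row[f"min_n_{eng}"] = res.label
        rows.append(row)
        logger.info("power table row %s done in %.1fs", preset.label, time.perf_counter() - t0)
    columns = [
        "procedure", "cl_max", "n_total", "n_rural", "rural_fraction",
        "p_event_rural", "p_event_referral", "power_mle", "power_firth",
        "mc_se_mle", "mc_se_firth", "failed_fits_mle",
    ]
    if include_min_n:
        columns += ["min_n_mle", "min_n_firth"]
    return pd.DataFrame(rows, columns=columns)
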