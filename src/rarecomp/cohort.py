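"""Synthetic patient-visit cohorts and adverse-event derivation.

The analyses in this package operate on a *cohort table*: one row per
patient visit, with a facility arm (``rural`` vs ``referral``), a CMG
comorbidity level (0-4), a binary adverse-event indicator, and adjustment
covariates.  This module provides

* :class:`ScenarioPreset` / :func:`table2_presets` -- per-procedure,
  per-risk-stratum scenario definitions (total volume, rural fraction,
  per-arm adverse-event proportions, covariate distributions) for the four
  low-acuity index procedures studied in rural surgical evaluation:
  hernia repair, appendectomy, colonoscopy and cesarean delivery;
* :func:`simulate_cohort` -- a seeded generator drawing visits per arm
  with Bernoulli events and independent (null-effect) covariates;
* :func:`detect_events` / :func:`combine_events` -- derivation of
  adverse-event indicators from coded hospital visits via a 30-day
  post-procedure window and aggregation into a combined any-event flag.

Covariates are simulated *independently* of the outcome (null effects):
the simulated facility effect is entirely carried by the per-arm event
proportions, which is the design the power analysis assumes.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "CovariateSpec",
    "ScenarioPreset",
    "CodedVisit",
    "table2_presets",
    "get_preset",
    "simulate_cohort",
    "detect_events",
    "combine_events",
]

logger = logging.getLogger(__name__)

ARMS = ("rural", "referral")

CONTINUOUS = "continuous-normal"
BINARY = "binary-bernoulli"


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one adjustment covariate, per arm.

    ``kind`` is ``"continuous-normal"`` (params ``(mean, sd)``) or
    ``"binary-bernoulli"`` (params ``(p,)``).  ``params`` maps each arm
    name to its parameter tuple; covariates may differ between arms but
    never affect the simulated outcome.
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        for arm in ARMS:
            if arm not in self.params:
                raise ValueError(f"covariate {self.name!r} missing params for arm {arm!r}")
            p = self.params[arm]
            if self.kind == CONTINUOUS:
                if len(p) != 2 or p[1] < 0:
                    raise ValueError(f"covariate {self.name!r}: need (mean, sd) with sd >= 0")
            else:
                if len(p) != 1 or not 0.0 <= p[0] <= 1.0:
                    raise ValueError(f"covariate {self.name!r}: need (prob,) with prob in [0,1]")

    @classmethod
    def normal(cls, name, mean, sd, *, referral_mean=None, referral_sd=None):
        """Continuous covariate; referral parameters default to the rural ones."""
        rm = mean if referral_mean is None else referral_mean
        rs = sd if referral_sd is None else referral_sd
        return cls(name, CONTINUOUS, {"rural": (mean, sd), "referral": (rm, rs)})

    @classmethod
    def bernoulli(cls, name, p, *, referral_p=None):
        rp = p if referral_p is None else referral_p
        return cls(name, BINARY, {"rural": (p,), "referral": (rp,)})

    def draw(self, arm: str, size: int, rng: np.random.Generator) -> np.ndarray:
        pars = self.params[arm]
        if self.kind == CONTINUOUS:
            return rng.normal(pars[0], pars[1], size)
        return rng.binomial(1, pars[0], size).astype(float)


@dataclass(frozen=True)
class ScenarioPreset:
    """One simulation scenario: a procedure restricted to comorbidity levels 0..cl_max.

    ``rural_fraction`` is the share of visits at rural facilities;
    ``p_event_rural`` / ``p_event_referral`` are the per-arm combined
    adverse-event proportions the generator treats as true.
    """

    procedure: str
    cl_max: int
    n_total: int
    rural_fraction: float
    p_event_rural: float
    p_event_referral: float
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.cl_max <= 4:
            raise ValueError("cl_max must be in 0..4")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0.0 < self.rural_fraction < 1.0:
            raise ValueError("rural_fraction must lie strictly in (0, 1)")
        for p in (self.p_event_rural, self.p_event_referral):
            if not 0.0 <= p <= 1.0:
                raise ValueError("event proportions must lie in [0, 1]")

    @property
    def n_rural(self) -> int:
        return int(round(self.rural_fraction * self.n_total))

    @property
    def label(self) -> str:
        return f"{self.procedure}[cl<={self.cl_max}]"


# Default covariate distributions per procedure.  The scenario tables give
# only volumes and event proportions; these marginals are package defaults
# chosen to be demographically plausible for each procedure.  They are null
# covariates (no outcome effect), so downstream power estimates do not
# depend on the particular values -- a property the test suite checks.
def _default_covariates(procedure: str) -> tuple:
    income = CovariateSpec.normal("income_decile", 5.5, 2.8)
    if procedure == "hernia":
        return (
            CovariateSpec.normal("age", 55.0, 17.0),
            CovariateSpec.bernoulli("sex_female", 0.25),
            income,
            CovariateSpec.bernoulli("laparoscopy", 0.5),
        )
    if procedure == "appendectomy":
        return (
            CovariateSpec.normal("age", 35.0, 18.0),
            CovariateSpec.bernoulli("sex_female", 0.5),
            income,
            CovariateSpec.bernoulli("laparoscopy", 0.8),
        )
    if procedure == "colonoscopy":
        return (
            CovariateSpec.normal("age", 60.0, 12.0),
            CovariateSpec.bernoulli("sex_female", 0.5),
            income,
        )
    if procedure == "cesarean":
        # All patients are female, so sex would be a constant column and is
        # excluded from the design.  Gravidity is approximated as normal.
        return (
            CovariateSpec.normal("age", 31.0, 5.0),
            income,
            CovariateSpec.normal("gravidity", 2.0, 1.2),
            CovariateSpec.bernoulli("emergency", 0.4),
        )
    raise ValueError(f"unknown procedure {procedure!r}")


# (procedure, cl_max) -> (n_total, n_rural, p_event_rural, p_event_referral),
# cumulative comorbidity strata: cl_max = k includes levels 0..k.
_SCENARIOS = {
    ("hernia", 0): (7460, 994, 0.012, 0.017),
    ("hernia", 1): (7634, 998, 0.012, 0.024),
    ("hernia", 2): (7706, 999, 0.012, 0.029),
    ("hernia", 3): (7753, 999, 0.012, 0.034),
    ("hernia", 4): (7792, 999, 0.012, 0.038),
    ("appendectomy", 0): (2392, 134, 0.030, 0.032),
    ("appendectomy", 1): (2534, 135, 0.037, 0.063),
    ("appendectomy", 2): (2587, 135, 0.037, 0.075),
    ("appendectomy", 3): (2607, 136, 0.044, 0.081),
    ("appendectomy", 4): (2613, 136, 0.044, 0.083),
    ("colonoscopy", 0): (51319, 10513, 0.004, 0.005),
    ("colonoscopy", 1): (51601, 10535, 0.005, 0.007),
    ("colonoscopy", 2): (51780, 10550, 0.005, 0.009),
    ("colonoscopy", 3): (51891, 10558, 0.005, 0.010),
    ("colonoscopy", 4): (51968, 10559, 0.005, 0.012),
    ("cesarean", 0): (5183, 852, 0.012, 0.015),
    ("cesarean", 1): (5801, 928, 0.016, 0.020),
    ("cesarean", 2): (5953, 937, 0.018, 0.021),
    ("cesarean", 3): (5962, 937, 0.018, 0.021),
    ("cesarean", 4): (5972, 937, 0.018, 0.021),
}

PROCEDURES = ("hernia", "appendectomy", "colonoscopy", "cesarean")


def get_preset(procedure: str, cl_max: int) -> ScenarioPreset:
    """Return the scenario preset for one procedure and cumulative risk stratum."""
    key = (procedure, cl_max)
    if key not in _SCENARIOS:
        raise KeyError(f"no preset for procedure={procedure!r}, cl_max={cl_max}")
    n_total, n_rural, p_r, p_c = _SCENARIOS[key]
    return ScenarioPreset(
        procedure=procedure,
        cl_max=cl_max,
        n_total=n_total,
        rural_fraction=n_rural / n_total,
        p_event_rural=p_r,
        p_event_referral=p_c,
        covariates=_default_covariates(procedure),
    )


def table2_presets() -> list:
    """All 20 presets: 4 index procedures x 5 cumulative comorbidity strata."""
    return [get_preset(proc, cl) for proc in PROCEDURES for cl in range(5)]


def _simulate_arrays(preset: ScenarioPreset, n: int, rng: np.random.Generator):
    """Fast path: return (y, arm01, covariate matrix, names) as numpy arrays.

    Rows are rural first, then referral.  Arm sizes use the deterministic
    split n_rural = round(f * n); events are per-row Bernoulli draws with
    the arm's event proportion; covariates are drawn independently per arm
    and carry no effect on the event.
    """
    n_rural = int(round(preset.rural_fraction * n))
    n_referral = n - n_rural
    if n_rural < 1 or n_referral < 1:
        raise ValueError(
            f"degenerate design: n={n} with rural_fraction={preset.rural_fraction:.4f} "
            f"places {n_rural} rural / {n_referral} referral visits; need >= 1 in each arm"
        )
    arm01 = np.concatenate([np.ones(n_rural), np.zeros(n_referral)])
    y = np.concatenate(
        [
            rng.binomial(1, preset.p_event_rural, n_rural),
            rng.binomial(1, preset.p_event_referral, n_referral),
        ]
    ).astype(float)
    names = [c.name for c in preset.covariates]
    cols = []
    for cov in preset.covariates:
        cols.append(
            np.concatenate([cov.draw("rural", n_rural, rng), cov.draw("referral", n_referral, rng)])
        )
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return y, arm01, X, names


def simulate_cohort(preset: ScenarioPreset, n: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate a cohort table of ``n`` visits (default: the preset's n_total).

    Returns a DataFrame with columns ``arm`` ("rural"/"referral"),
    ``comorbidity_level`` (uniform over 0..cl_max; a bookkeeping label, the
    stratum is already fixed by the preset), ``event`` (0/1) and one column
    per covariate.  Deterministic given ``seed``.
    """
    if n is None:
        n = preset.n_total
    if n < 2:
        raise ValueError("need n >= 2 to place at least one visit in each arm")
    rng = np.random.default_rng(seed)
    y, arm01, X, names = _simulate_arrays(preset, n, rng)
    cl = rng.integers(0, preset.cl_max + 1, n)
    data = {
        "arm": np.where(arm01 == 1.0, "rural", "referral"),
        "comorbidity_level": cl,
        "event": y.astype(int),
    }
    for j, name in enumerate(names):
        data[name] = X[:, j]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Adverse-event derivation from coded visits


@dataclass(frozen=True)
class CodedVisit:
    """One hospital visit abstract: diagnosis and intervention code lists.

    Real abstracts carry up to 25 diagnosis and 20 intervention codes; the
    lists here may be any length, including empty.
    """

    patient_id: str
    date: _dt.date
    diagnosis_codes: tuple = ()
    intervention_codes: tuple = ()

    @property
    def all_codes(self) -> tuple:
        return tuple(self.diagnosis_codes) + tuple(self.intervention_codes)


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValueError(f"unparseable visit date {value!r} (expected ISO-8601)") from exc


def _matches(code: str, code_set) -> bool:
    # Code-set entries are prefixes of recorded codes: "T810" matches "T8102".
    return any(code.startswith(prefix) for prefix in code_set)


def detect_events(
    index_visits,
    all_visits,
    code_sets: dict,
    window_days: int = 30,
    include_index_day: bool = True,
) -> pd.DataFrame:
    """Flag adverse events occurring within ``window_days`` of each index visit.

    For each index visit and each named event, the indicator is 1 iff some
    visit of the same patient dated within the window carries a code whose
    prefix appears in that event's code set.  The window is inclusive on
    both ends: days 0..window_days after the index date (day 0 excluded
    when ``include_index_day`` is false, for analyses that do not want the
    index visit's own codes to count).

    Returns a DataFrame with one row per index visit (in input order) and
    one 0/1 column per event name.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    index_visits = list(index_visits)
    index_patients = {v.patient_id for v in index_visits}
    by_patient: dict = {}
    for v in all_visits:
        d = _as_date(v.date)
        if v.patient_id not in index_patients:
            logger.warning("visit for patient %r has no index visit; ignored", v.patient_id)
            continue
        by_patient.setdefault(v.patient_id, []).append((d, v.all_codes))

    names = list(code_sets)
    out = np.zeros((len(index_visits), len(names)), dtype=int)
    lo_offset = 0 if include_index_day else 1
    for i, iv in enumerate(index_visits):
        d0 = _as_date(iv.date)
        lo = d0 + _dt.timedelta(days=lo_offset)
        hi = d0 + _dt.timedelta(days=window_days)
        for d, codes in by_patient.get(iv.patient_id, []):
            if not lo <= d <= hi:
                continue
            for j, name in enumerate(names):
                if out[i, j] == 0 and any(_matches(c, code_sets[name]) for c in codes):
                    out[i, j] = 1
    return pd.DataFrame(out, columns=names)


def combine_events(indicators: pd.DataFrame) -> pd.Series:
    """Row-wise logical OR of individual event indicators: the combined any-event flag."""
    if indicators.shape[1] < 1:
        raise ValueError("need at least one indicator column")
    return indicators.any(axis=1).astype(int).rename("event")
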