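"""Binary-outcome regression by plain and Firth-penalized maximum likelihood.

Rare, imbalanced adverse-event data invite (quasi-)separation: a covariate
pattern that perfectly predicts the outcome, under which the ordinary
maximum-likelihood logistic estimate diverges.  Firth's remedy maximizes
the *penalized* log-likelihood

    l*(beta) = l(beta) + 0.5 * log det I(beta),

where I(beta) = X' W X is the Fisher information (W the diagonal of
pi_i (1 - pi_i)).  The penalty is the Jeffreys invariant prior; its score
contribution works out to adding h_i (1/2 - pi_i) to each residual, with
h_i the hat-matrix diagonal of the weighted design.  The penalized
estimate is finite for every dataset, including complete separation and
all-one-class outcomes, and is bias-reduced for rare events.

Both engines share one Newton-with-step-halving core.  Hypothesis tests on
a single coefficient are provided as Wald tests (normal reference on
(estimate - null) / SE) and, for the Firth engine, penalized likelihood
ratio tests against a constrained refit with the coefficient held at the
null value.  One-sided penalized LRT p-values use the signed-root
convention: the chi-square p is halved on the side of the alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "DesignSpec",
    "FitResult",
    "TestResult",
    "build_design",
    "fit_logistic",
    "fit_firth",
    "wald_test",
    "penalized_lrt",
    "SeparationError",
]

logger = logging.getLogger(__name__)

INTERCEPT = "(intercept)"

MAX_ITER = 100
TOL = 1e-8
# MLE separation heuristics: a diverging slope coefficient (a log odds ratio
# beyond ~15 means a perfectly-predicting covariate pattern), or every
# working weight collapsing to zero (all fitted probabilities at 0/1).
SEP_COEF_NORM = 15.0
SEP_MIN_WEIGHT = 1e-6


class SeparationError(RuntimeError):
    """Raised when an operation requires a finite MLE that does not exist."""


@dataclass(frozen=True)
class DesignSpec:
    """Model specification: outcome ~ treatment + covariates (+ intercept).

    The treatment column is the binary arm indicator whose coefficient is
    the adjusted log odds ratio of interest (rural = 1, referral = 0 for
    string-labelled arms).
    """

    outcome: str = "event"
    treatment: str = "arm"
    covariates: tuple = ()
    intercept: bool = True

    def __post_init__(self) -> None:
        cols = [self.outcome, self.treatment, *self.covariates]
        if len(set(cols)) != len(cols):
            raise ValueError("duplicated column names in design")

    @property
    def columns(self) -> list:
        """Design-matrix column names, in order."""
        names = [INTERCEPT] if self.intercept else []
        return names + [self.treatment, *self.covariates]


@dataclass
class FitResult:
    """Fitted coefficients on the log-odds scale, with inference byproducts."""

    engine: str
    params: pd.Series
    bse: pd.Series
    loglik: float              # penalized log-likelihood when engine == "firth"
    converged: bool
    n_iter: int
    separation_flag: bool = False
    cov_params: np.ndarray | None = None
    n_obs: int = 0

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "iterations": int(self.n_iter),
            "separation_flag": bool(self.separation_flag),
            "n_obs": int(self.n_obs),
        }


@dataclass(frozen=True)
class TestResult:
    """A single-coefficient hypothesis test result."""

    kind: str
    statistic: float
    p_value: float
    null_value: float
    estimate: float
    sided: str

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "null_value": self.null_value,
            "estimate": self.estimate,
            "sided": self.sided,
        }


def _encode_binary(values: np.ndarray, name: str) -> np.ndarray:
    """Coerce a column to 0/1 floats; string arms map rural -> 1, referral -> 0."""
    if values.dtype == object or values.dtype.kind in "US":
        labels = set(np.unique(values).tolist())
        if labels <= {"rural", "referral"}:
            return (values == "rural").astype(float)
        raise ValueError(f"column {name!r} has non-binary labels {sorted(labels)}")
    arr = np.asarray(values, dtype=float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError(f"column {name!r} must be binary 0/1")
    return arr


def build_design(cohort: pd.DataFrame, design: DesignSpec):
    """Return (y, X, names) numpy design pieces for a cohort table."""
    for col in (design.outcome, design.treatment, *design.covariates):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing required column {col!r}")
    y = _encode_binary(cohort[design.outcome].to_numpy(), design.outcome)
    cols = []
    if design.intercept:
        cols.append(np.ones(len(cohort)))
    cols.append(_encode_binary(cohort[design.treatment].to_numpy(), design.treatment))
    for name in design.covariates:
        cols.append(np.asarray(cohort[name].to_numpy(), dtype=float))
    X = np.column_stack(cols)
    return y, X, design.columns


def _loglik(y, eta):
    # Numerically stable Bernoulli log-likelihood: sum y*eta - log(1 + e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _penalized_loglik(y, eta, X):
    pi = expit(eta)
    w = pi * (1.0 - pi)
    XtWX = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return _loglik(y, eta) + 0.5 * logdet


def _check_columns(X, names, intercept):
    """Reject constant non-intercept columns and rank-deficient designs."""
    start = 1 if intercept else 0
    for j in range(start, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"covariate column {names[j]!r} is constant")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        dep = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"design matrix is rank-deficient; dependent columns: {dep or names}")


def _newton(y, X, *, penalty: bool, free: np.ndarray, beta0: np.ndarray,
            max_iter: int = MAX_ITER, tol: float = TOL):
    """Newton iteration on the (penalized) likelihood with step-halving.

    ``free`` is a boolean mask of coefficients being estimated; the rest
    stay at their ``beta0`` values (used by constrained refits).  The
    Firth-modified score over the free coordinates is

        U*_r = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ir,

    with h_i the hat diagonal of the weighted *full* design, so the
    penalty of a constrained fit keeps the information of the fixed
    column.  The plain MLE uses the same iteration with h_i = 0.
    """
    n, p = X.shape
    beta = beta0.copy()
    Xf = X[:, free]
    objective = _penalized_loglik if penalty else (lambda yy, ee, XX: _loglik(yy, ee))
    ll = objective(y, X @ beta, X)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        pi = expit(eta)
        w = pi * (1.0 - pi)
        resid = y - pi
        if penalty:
            XtWX = (X * w[:, None]).T @ X
            try:
                # h_i = w_i * x_i' (X'WX)^{-1} x_i
                h = w * np.einsum("ij,ij->i", X, np.linalg.solve(XtWX, X.T).T)
            except np.linalg.LinAlgError:
                h = np.zeros(n)
            resid = resid + h * (0.5 - pi)
        score = Xf.T @ resid
        info = (Xf * w[:, None]).T @ Xf
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        # step-halving until the objective does not decrease
        new_beta = beta.copy()
        for k in range(31):
            trial = beta.copy()
            trial[free] = beta[free] + step / (2**k)
            ll_trial = objective(y, X @ trial, X)
            if not penalty or ll_trial >= ll - 1e-12:
                new_beta, ll = trial, ll_trial
                break
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if not np.isfinite(beta).all():
            beta = np.nan_to_num(beta, nan=0.0, posinf=SEP_COEF_NORM * 10, neginf=-SEP_COEF_NORM * 10)
            converged = False
            break
        if delta < tol:
            converged = True
            break
    if penalty and not converged:
        # Degenerate tables (zero cells) make the approximate Newton step
        # creep; polish with BFGS on the exact penalized-likelihood gradient.
        beta, ll, converged = _bfgs_polish(y, X, free, beta)
    eta = X @ beta
    pi = expit(eta)
    w = pi * (1.0 - pi)
    info_full = (X * w[:, None]).T @ X
    return beta, ll, converged, n_iter, w, info_full


def _modified_score(y, X, free, beta):
    """Exact gradient of the penalized log-likelihood in the free coordinates."""
    pi = expit(X @ beta)
    w = pi * (1.0 - pi)
    XtWX = (X * w[:, None]).T @ X
    try:
        h = w * np.einsum("ij,ij->i", X, np.linalg.solve(XtWX, X.T).T)
    except np.linalg.LinAlgError:
        h = np.zeros(len(y))
    return X[:, free].T @ (y - pi + h * (0.5 - pi))


def _bfgs_polish(y, X, free, beta):
    from scipy.optimize import minimize

    base = beta.copy()

    def unpack(bf):
        full = base.copy()
        full[free] = bf
        return full

    res = minimize(
        lambda bf: -_penalized_loglik(y, X @ unpack(bf), X),
        beta[free],
        jac=lambda bf: -_modified_score(y, X, free, unpack(bf)),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    polished = unpack(res.x)
    score = _modified_score(y, X, free, polished)
    converged = bool(np.max(np.abs(score)) < 1e-6) if score.size else True
    return polished, -float(res.fun), converged


def _fit_core(y, X, names, *, engine: str, check: bool = True) -> FitResult:
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    intercept = names[0] == INTERCEPT
    if check:
        _check_columns(X, names, intercept)
    n_events = int(y.sum())
    if engine == "mle" and n_events in (0, n):
        raise SeparationError(
            "outcome has a single class; the maximum-likelihood estimate does not exist "
            "(use the firth engine)"
        )
    penalty = engine == "firth"
    free = np.ones(p, dtype=bool)
    beta0 = np.zeros(p)
    if intercept:
        # warm start at the marginal log-odds (Haldane-smoothed)
        beta0[0] = np.log((n_events + 0.5) / (n - n_events + 0.5))
    beta, ll, converged, n_iter, w, info = _newton(
        y, X, penalty=penalty, free=free, beta0=beta0
    )
    separation = False
    if engine == "mle":
        slopes = beta[1:] if intercept else beta
        if (slopes.size and np.max(np.abs(slopes)) > SEP_COEF_NORM) or (
            w.size and w.max() < SEP_MIN_WEIGHT
        ):
            separation = True
        if not converged:
            separation = separation or np.max(np.abs(beta)) > 10.0
        if separation:
            converged = False
            logger.warning(
                "logistic MLE shows (quasi-)separation; coefficients reported at the "
                "last iterate are not maximum-likelihood estimates"
            )
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        bse = np.full(p, np.nan)
    return FitResult(
        engine=engine,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        loglik=ll,
        converged=converged,
        n_iter=max(n_iter, 1),
        separation_flag=separation,
        cov_params=cov,
        n_obs=n,
    )


def fit_logistic(cohort: pd.DataFrame, design: DesignSpec) -> FitResult:
    """Ordinary maximum-likelihood logistic regression (IRLS/Newton).

    Under complete or quasi separation the maximum does not exist; the fit
    is then flagged (``separation_flag=True``, ``converged=False``) and the
    last iterate is reported with a warning.
    """
    y, X, names = build_design(cohort, design)
    return _fit_core(y, X, names, engine="mle")


def fit_firth(cohort: pd.DataFrame, design: DesignSpec) -> FitResult:
    """Firth-penalized logistic regression; finite estimates on every dataset."""
    y, X, names = build_design(cohort, design)
    return _fit_core(y, X, names, engine="firth")


def _one_sided_p(z: float, sided: str) -> float:
    if sided == "two-sided":
        return 2.0 * stats.norm.sf(abs(z))
    if sided == "greater":
        return float(stats.norm.sf(z))
    if sided == "less":
        return float(stats.norm.cdf(z))
    raise ValueError(f"sided must be 'two-sided', 'greater' or 'less', got {sided!r}")


def wald_test(fit: FitResult, coefficient: str, null_value: float = 0.0,
              sided: str = "two-sided") -> TestResult:
    """Wald test of a point null on one coefficient, normal reference."""
    if coefficient not in fit.params.index:
        raise KeyError(f"no coefficient {coefficient!r} in fit")
    est = float(fit.params[coefficient])
    se = float(fit.bse[coefficient])
    if not se > 0.0:
        raise ValueError(f"standard error for {coefficient!r} is zero; Wald test undefined")
    if fit.separation_flag:
        logger.warning("Wald test on a separated fit is unreliable")
    z = (est - null_value) / se
    return TestResult(
        kind=f"wald-{'two-sided' if sided == 'two-sided' else 'one-sided'}",
        statistic=z,
        p_value=_one_sided_p(z, sided),
        null_value=null_value,
        estimate=est,
        sided=sided,
    )


def _plrt_core(y, X, names, coefficient: str, null_value: float, sided: str,
               full_fit: FitResult | None = None) -> TestResult:
    if coefficient not in names:
        raise KeyError(f"no coefficient {coefficient!r} in design")
    j = names.index(coefficient)
    if full_fit is None or full_fit.engine != "firth":
        full_fit = _fit_core(y, X, names, engine="firth", check=False)
    p = X.shape[1]
    free = np.ones(p, dtype=bool)
    free[j] = False
    # warm start the constrained refit from the unconstrained solution
    beta0 = full_fit.params.to_numpy().copy()
    beta0[j] = null_value
    beta_c, ll_c, conv_c, _, _, _ = _newton(y, X, penalty=True, free=free, beta0=beta0)
    if not conv_c:
        raise RuntimeError(
            f"constrained Firth refit at {coefficient}={null_value} failed to converge "
            f"(last penalized loglik {ll_c:.6g})"
        )
    stat = max(2.0 * (full_fit.loglik - ll_c), 0.0)
    est = float(full_fit.params.iloc[j])
    if sided == "two-sided":
        pval = float(stats.chi2.sf(stat, df=1))
        kind = "plrt-two-sided"
    else:
        # signed-root: z = sign(est - null) * sqrt(stat), normal reference
        z = np.sign(est - null_value) * np.sqrt(stat)
        pval = _one_sided_p(float(z), sided)
        kind = "plrt-one-sided"
    return TestResult(
        kind=kind, statistic=stat, p_value=pval,
        null_value=null_value, estimate=est, sided=sided,
    )


def penalized_lrt(cohort: pd.DataFrame, design: DesignSpec, coefficient: str | None = None,
                  null_value: float = 0.0, sided: str = "two-sided") -> TestResult:
    """Penalized likelihood-ratio test of one coefficient at a point null.

    The statistic is 2*(l*(full) - l*(constrained)) where the constrained
    fit maximizes the penalized likelihood with the named coefficient held
    at ``null_value`` (via an offset; the Jeffreys penalty keeps the full
    design's information).  Two-sided p-values use chi-square with 1 df;
    one-sided p-values use the signed-root convention.
    """
    y, X, names = build_design(cohort, design)
    if coefficient is None:
        coefficient = design.treatment
    return _plrt_core(y, X, names, coefficient, null_value, sided)
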