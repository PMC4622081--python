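"""Cox proportional hazards regression with Breslow tie handling.

The partial log-likelihood is maximized by Newton-Raphson with
step-halving.  For each distinct event time ``t`` with event set ``D_t``
and risk set ``R_t`` the Breslow contribution is

    sum_{i in D_t} eta_i  -  |D_t| * log( sum_{j in R_t} exp(eta_j) )

with ``eta = X beta`` the linear predictor (risk score).  Tied event times
share a single risk-set denominator.

The module also provides Schoenfeld-residual diagnostics for the
proportional hazards assumption: the residual of an event is the failing
patient's covariate vector minus the risk-set mean weighted by
``exp(eta)``; each column's residuals are correlated against the rank of
the event time, a departure from zero correlation indicating a
time-varying effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel_io import DesignMatrix, SurvivalOutcome
from .errors import DivergenceError, EstimationError

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 50
MAX_HALVINGS = 20
DIVERGENCE_BOUND = 20.0


@dataclass(frozen=True)
class CoxFit:
    """Result of a Breslow partial-likelihood maximization."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    loglik_null: float
    loglik_final: float
    converged: bool
    iterations: int
    linear_predictors: np.ndarray
    column_names: tuple[str, ...]
    ridged: bool = False  # singular information stabilized by a tiny ridge

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)


@dataclass(frozen=True)
class SchoenfeldDiagnostics:
    """Per-event Schoenfeld residuals and correlation-with-time tests."""

    residuals: np.ndarray  # (n_events, p), ordered by event time
    event_times: np.ndarray
    per_column_pvalue: np.ndarray
    global_pvalue: float
    column_names: tuple[str, ...]


class BreslowData:
    """Outcome-sorted scaffolding reused across refits of the same outcome.

    Rows are sorted by ascending time; tied times share a risk set that
    starts at the first row of the tie group.
    """

    __slots__ = (
        "n", "order", "time", "event", "X",
        "event_rows", "grp_of_event", "group_end", "n_events",
    )

    def __init__(self, X: np.ndarray, outcome: SurvivalOutcome):
        time = outcome.time
        order = np.argsort(time, kind="stable")
        self.n = time.shape[0]
        self.order = order
        self.time = time[order]
        self.event = outcome.event[order].astype(bool)
        self.X = np.ascontiguousarray(np.asarray(X, dtype=float)[order])
        # first and last index of each tie group
        starts = np.r_[0, np.flatnonzero(np.diff(self.time)) + 1]
        sizes = np.diff(np.r_[starts, self.n])
        group_start = np.repeat(starts, sizes)
        self.group_end = np.repeat(starts + sizes - 1, sizes)
        self.event_rows = np.flatnonzero(self.event)
        self.grp_of_event = group_start[self.event_rows]
        self.n_events = self.event_rows.shape[0]
        if self.n_events == 0:
            raise EstimationError("no observed events; Cox model cannot be estimated")

    def replace_matrix(self, X: np.ndarray) -> "BreslowData":
        """Same outcome scaffolding, new covariate matrix (already row-aligned)."""
        new = object.__new__(BreslowData)
        for name in self.__slots__:
            object.__setattr__(new, name, getattr(self, name))
        new.X = np.ascontiguousarray(np.asarray(X, dtype=float)[self.order])
        return new


def _rcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def breslow_loglik(bd: BreslowData, beta: np.ndarray) -> float:
    eta = bd.X @ beta if beta.size else np.zeros(bd.n)
    m = eta.max() if bd.n else 0.0
    w = np.exp(eta - m)
    s0 = _rcumsum(w)[bd.grp_of_event]
    return float(eta[bd.event_rows].sum() - np.log(s0).sum() - m * bd.n_events)


def _loglik_grad_info(bd: BreslowData, beta: np.ndarray):
    """Breslow partial loglik, score vector and observed information."""
    X = bd.X
    eta = X @ beta
    m = eta.max()
    w = np.exp(eta - m)
    S0 = _rcumsum(w)
    s0e = S0[bd.grp_of_event]
    ll = float(eta[bd.event_rows].sum() - np.log(s0e).sum() - m * bd.n_events)
    S1 = _rcumsum(w[:, None] * X)
    mu = S1[bd.grp_of_event] / s0e[:, None]  # (n_events, p)
    grad = X[bd.event_rows].sum(axis=0) - mu.sum(axis=0)
    # Sum_e S2(t_e)/S0(t_e) = X' diag(w * a) X with a_i the cumulative
    # 1/S0 over events whose risk set contains row i (suffix risk sets
    # make this a prefix sum over tie groups) — two GEMMs instead of an
    # O(n p^2) tensor cumsum.
    c = np.zeros(bd.n)
    c[bd.event_rows] = 1.0 / s0e
    a = np.cumsum(c)[bd.group_end]
    info = (X * (w * a)[:, None]).T @ X - mu.T @ mu
    return ll, grad, info, mu


def _fit_prepared(
    bd: BreslowData,
    column_names: tuple[str, ...],
    tolerance: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CoxFit:
    p = bd.X.shape[1]
    loglik_null = breslow_loglik(bd, np.zeros(p))
    # constant columns carry no information (the partial likelihood is
    # invariant under translation); hold their coefficients at zero
    active = bd.X.std(axis=0) > 1e-12
    if p and not active.all():
        sub = object.__new__(BreslowData)
        for name in BreslowData.__slots__:
            object.__setattr__(sub, name, getattr(bd, name))
        sub.X = np.ascontiguousarray(bd.X[:, active])
        fit_sub = _fit_prepared(
            sub,
            tuple(c for c, a in zip(column_names, active) if a),
            tolerance,
            max_iter,
        )
        coef = np.zeros(p)
        coef[active] = fit_sub.coefficients
        se = np.zeros(p)
        se[active] = fit_sub.standard_errors
        return CoxFit(
            coefficients=coef,
            standard_errors=se,
            loglik_null=loglik_null,
            loglik_final=fit_sub.loglik_final,
            converged=fit_sub.converged,
            iterations=fit_sub.iterations,
            linear_predictors=fit_sub.linear_predictors,
            column_names=column_names,
            ridged=True,  # flag: design was degenerate
        )
    if p == 0:
        return CoxFit(
            coefficients=np.empty(0),
            standard_errors=np.empty(0),
            loglik_null=loglik_null,
            loglik_final=loglik_null,
            converged=True,
            iterations=0,
            linear_predictors=np.zeros(bd.n),
            column_names=column_names,
        )
    beta = np.zeros(p)
    ll = loglik_null
    converged = False
    ridged = False
    info = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        ll, grad, info, _ = _loglik_grad_info(bd, beta)
        if np.max(np.abs(grad)) < tolerance:
            converged = True
            iterations -= 1
            break
        try:
            delta = np.linalg.solve(info, grad)
            # a wild step signals a (near-)singular information matrix,
            # e.g. a constant or collinear column; retry stabilized
            if not np.all(np.isfinite(delta)) or np.max(np.abs(delta)) > 1e3:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            ridged = True
            ridge = 1e-8 * max(float(np.max(np.abs(np.diag(info)))), 1.0)
            delta = np.linalg.solve(info + ridge * np.eye(p), grad)
        step = 1.0
        for _ in range(MAX_HALVINGS):
            cand = beta + step * delta
            ll_new = breslow_loglik(bd, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            cand, ll_new = beta, ll  # no improving step found
        beta, ll = cand, ll_new
        if np.max(np.abs(beta)) > DIVERGENCE_BOUND:
            j = int(np.argmax(np.abs(beta)))
            raise DivergenceError(column_names[j], DIVERGENCE_BOUND)
    if info is None:
        _, _, info, _ = _loglik_grad_info(bd, beta)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ridged = True
        ridge = 1e-8 * max(float(np.max(np.abs(np.diag(info)))), 1.0)
        se = np.sqrt(np.clip(np.diag(np.linalg.inv(info + ridge * np.eye(p))), 0.0, None))
    eta_sorted = bd.X @ beta
    lp = np.empty(bd.n)
    lp[bd.order] = eta_sorted
    return CoxFit(
        coefficients=beta,
        standard_errors=se,
        loglik_null=loglik_null,
        loglik_final=ll,
        converged=converged,
        iterations=iterations,
        linear_predictors=lp,
        column_names=column_names,
        ridged=ridged,
    )


def fit_cox(
    design: DesignMatrix,
    outcome: SurvivalOutcome,
    tolerance: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CoxFit:
    """Maximize the Breslow partial likelihood for the given design.

    Raises
    ------
    EstimationError
        If there are no observed events or fewer than two patients.
    DivergenceError
        If a coefficient passes the divergence bound (monotone
        likelihood, e.g. a column perfectly separating the event order).
    """
    X = np.asarray(design.matrix, dtype=float)
    if X.shape[0] < 2:
        raise EstimationError("need at least 2 patients")
    if not np.all(np.isfinite(X)):
        raise EstimationError("design matrix contains non-finite values")
    bd = BreslowData(X, outcome)
    return _fit_prepared(bd, tuple(design.column_names), tolerance, max_iter)


def risk_scores(fit: CoxFit, design: DesignMatrix) -> np.ndarray:
    """Linear predictors ``X beta`` — a monotone transform of predicted hazard."""
    X = np.asarray(design.matrix, dtype=float)
    if X.shape[1] != fit.coefficients.shape[0]:
        raise EstimationError(
            f"design has {X.shape[1]} columns but fit has {fit.coefficients.shape[0]}"
        )
    if fit.coefficients.size == 0:
        return np.zeros(X.shape[0])
    return X @ fit.coefficients


def schoenfeld_test(
    fit: CoxFit, design: DesignMatrix, outcome: SurvivalOutcome
) -> SchoenfeldDiagnostics:
    """Schoenfeld residuals and correlation-with-time-rank tests.

    Per-column p-values come from the Pearson correlation between the
    column's residuals and the rank of the event time.  The global
    statistic sums the squared per-column t-statistics and is referred to
    a chi-square with p degrees of freedom — an approximation that treats
    columns as independent.
    """
    bd = BreslowData(np.asarray(design.matrix, dtype=float), outcome)
    if bd.n_events < 3:
        raise EstimationError("Schoenfeld diagnostics need at least 3 events")
    _, _, _, mu = _loglik_grad_info(bd, fit.coefficients)
    resid = bd.X[bd.event_rows] - mu  # ordered by ascending event time
    etimes = bd.time[bd.event_rows]
    g = stats.rankdata(etimes)
    m, p = resid.shape
    pvals = np.ones(p)
    tstats = np.zeros(p)
    for j in range(p):
        col = resid[:, j]
        if np.std(col) < 1e-12 or np.std(g) < 1e-12:
            continue
        r, pv = stats.pearsonr(col, g)
        pvals[j] = pv
        with np.errstate(divide="ignore"):
            tstats[j] = r * np.sqrt(m - 2) / np.sqrt(max(1 - r * r, 1e-12))
    chi2 = float(np.sum(tstats**2))
    global_p = float(stats.chi2.sf(chi2, df=p)) if p else 1.0
    return SchoenfeldDiagnostics(
        residuals=resid,
        event_times=etimes,
        per_column_pvalue=pvals,
        global_pvalue=global_p,
        column_names=fit.column_names,
    )
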