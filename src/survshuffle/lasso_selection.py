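"""L1-penalized Cox regression for feature selection.

The penalized criterion is the Breslow partial log-likelihood minus
``lambda * sum_j |beta_j|``, with design columns standardized to zero
mean and unit variance before penalization (so AQUA-scale intensities
and 0/1 indicators are shrunk comparably) and coefficients reported back
on the original scale.  Each indicator column of a categorical variable
is penalized separately.

Optimization is proximal Newton: at each outer step the smooth part is
replaced by its local quadratic model (score and observed information
from the Breslow likelihood) and the penalized quadratic is solved by
cyclic coordinate descent with soft-thresholding, followed by a
step-halving line search on the true penalized objective.  Convergence
is declared on the Karush-Kuhn-Tucker conditions.

The sparsity parameter is chosen by likelihood cross-validation: for
each fold the path is fit on the training patients and scored by the
verification likelihood  loglik(all data at the fold's beta) -
loglik(training data at the fold's beta).  Selected features are meant
to be refit UNPENALIZED downstream (see :mod:`survshuffle.crossval` and
the workflow in :mod:`survshuffle.cli`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coxph import BreslowData, _loglik_grad_info, breslow_loglik
from .datamodel_io import DesignMatrix, SurvivalOutcome
from .errors import EstimationError

LAMBDA_LO = 0.001
LAMBDA_HI = 50.0
KKT_TOL = 1e-7


@dataclass(frozen=True)
class SelectionResult:
    lambda_chosen: float
    selected: tuple[str, ...]
    path: tuple[tuple[float, float], ...]  # (lambda, mean CV verification loglik)
    folds: int
    coefficients: np.ndarray  # original-scale coefficients at lambda_chosen
    column_names: tuple[str, ...]


def default_lambda_grid(num: int = 100) -> np.ndarray:
    """Log-spaced grid strictly inside (0.001, 50)."""
    return np.geomspace(LAMBDA_LO, LAMBDA_HI, num + 2)[1:-1]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 1e-12
    Z = np.where(ok, (X - mean) / np.where(ok, sd, 1.0), 0.0)
    return Z, sd, ok


def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def _fit_one_lambda(
    bd: BreslowData, lam: float, beta0: np.ndarray, max_outer: int = 100
) -> tuple[np.ndarray, bool]:
    """Proximal-Newton L1 solve at one lambda, warm-started at beta0."""
    p = beta0.shape[0]
    beta = beta0.copy()
    for _ in range(max_outer):
        ll, g, H, _ = _loglik_grad_info(bd, beta)
        # KKT: for the max problem, gradient of loglik must satisfy
        # |g_j| <= lam at zeros and g_j = lam * sign(beta_j) at nonzeros
        kkt = True
        for j in range(p):
            if beta[j] == 0.0:
                if abs(g[j]) > lam + KKT_TOL:
                    kkt = False
                    break
            elif abs(g[j] - lam * np.sign(beta[j])) > KKT_TOL:
                kkt = False
                break
        if kkt:
            return beta, True
        # inner CD on the penalized quadratic model (minimization form)
        b = beta.copy()
        Hd = np.zeros(p)  # H @ (b - beta)
        for _ in range(200):
            max_change = 0.0
            for j in range(p):
                hjj = H[j, j]
                if hjj <= 1e-12:
                    continue
                # smooth-part gradient of the quadratic at current b
                gj = -g[j] + Hd[j]
                z = hjj * b[j] - gj
                new = _soft(z, lam) / hjj
                if new != b[j]:
                    delta = new - b[j]
                    Hd += H[:, j] * delta
                    b[j] = new
                    max_change = max(max_change, abs(delta))
            if max_change < 1e-11:
                break
        direction = b - beta
        if np.max(np.abs(direction)) < 1e-12:
            return beta, False  # CD stalled without meeting KKT
        f0 = -ll + lam * np.abs(beta).sum()
        step = 1.0
        accepted = False
        for _ in range(30):
            cand = beta + step * direction
            fc = -breslow_loglik(bd, cand) + lam * np.abs(cand).sum()
            if np.isfinite(fc) and fc <= f0 + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return beta, False
        beta = cand
    return beta, False


def lambda_max(design: DesignMatrix, outcome: SurvivalOutcome) -> float:
    """Smallest penalty that zeroes every coefficient: the max-norm of the
    null-model score on the standardized design."""
    Z, _, _ = _standardize(np.asarray(design.matrix, dtype=float))
    bd = BreslowData(Z, outcome)
    _, g, _, _ = _loglik_grad_info(bd, np.zeros(Z.shape[1]))
    return float(np.max(np.abs(g))) if g.size else 0.0


def lasso_cox_path(
    design: DesignMatrix,
    outcome: SurvivalOutcome,
    lambda_grid: np.ndarray,
) -> list[np.ndarray | None]:
    """Coefficient vectors (original scale) along the penalty grid.

    The path is solved from the largest penalty down with warm starts;
    grid points whose solve fails to converge yield ``None``.  Output
    order matches the input grid order.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid <= 0):
        raise EstimationError("penalties must be positive")
    X = np.asarray(design.matrix, dtype=float)
    Z, sd, ok = _standardize(X)
    bd = BreslowData(Z, outcome)
    p = Z.shape[1]
    desc = np.argsort(-lambda_grid)
    out: list[np.ndarray | None] = [None] * lambda_grid.shape[0]
    beta = np.zeros(p)
    for idx in desc:
        beta, converged = _fit_one_lambda(bd, float(lambda_grid[idx]), beta)
        if converged:
            orig = np.where(ok, beta / np.where(ok, sd, 1.0), 0.0)
            out[idx] = orig
        else:
            beta = np.zeros(p)  # restart warm chain after a failure
    return out


def _path_standardized(
    bd: BreslowData, lambda_grid_desc: np.ndarray
) -> list[np.ndarray | None]:
    p = bd.X.shape[1]
    beta = np.zeros(p)
    out: list[np.ndarray | None] = []
    for lam in lambda_grid_desc:
        beta, converged = _fit_one_lambda(bd, float(lam), beta)
        out.append(beta.copy() if converged else None)
        if not converged:
            beta = np.zeros(p)
    return out


def select_features(
    design: DesignMatrix,
    outcome: SurvivalOutcome,
    folds: int = 10,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> SelectionResult:
    """Choose the penalty by k-fold likelihood cross-validation and return
    the nonzero feature set at that penalty.

    An empty selection (every coefficient zero at the chosen penalty) is a
    valid outcome, not an error.
    """
    if folds < 2:
        raise EstimationError("need at least 2 folds")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]  # descending
    X = np.asarray(design.matrix, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)
    full_bd = BreslowData(X, outcome)
    cv_scores = np.zeros(lambda_grid.shape[0])
    cv_counts = np.zeros(lambda_grid.shape[0], dtype=int)
    for held in fold_ids:
        train = np.setdiff1d(np.arange(n), held)
        Xtr = X[train]
        out_tr = SurvivalOutcome(outcome.time[train], outcome.event[train])
        if out_tr.n_events == 0:
            continue
        Ztr, sd_tr, ok_tr = _standardize(Xtr)
        bd_tr = BreslowData(Ztr, out_tr)
        path = _path_standardized(bd_tr, lambda_grid)
        ll_train_raw = BreslowData(Xtr, out_tr)
        for k, beta_std in enumerate(path):
            if beta_std is None:
                continue
            beta_orig = np.where(ok_tr, beta_std / np.where(ok_tr, sd_tr, 1.0), 0.0)
            ll_full = breslow_loglik(full_bd, beta_orig)
            ll_tr = breslow_loglik(ll_train_raw, beta_orig)
            cv_scores[k] += ll_full - ll_tr
            cv_counts[k] += 1
    valid = cv_counts == folds
    if not valid.any():
        raise EstimationError("cross-validation failed at every penalty")
    mean_scores = np.where(valid, cv_scores / np.maximum(cv_counts, 1), -np.inf)
    best = int(np.argmax(mean_scores))  # ties -> largest penalty (sparser model)
    lam_best = float(lambda_grid[best])
    final = lasso_cox_path(design, outcome, np.array([lam_best]))[0]
    if final is None:
        raise EstimationError(f"final solve failed at lambda = {lam_best}")
    selected = tuple(
        name for name, b in zip(design.column_names, final) if b != 0.0
    )
    path_pairs = tuple(
        (float(lam), float(s))
        for lam, s, v in zip(lambda_grid, mean_scores, valid)
        if v
    )
    return SelectionResult(
        lambda_chosen=lam_best,
        selected=selected,
        path=path_pairs,
        folds=folds,
        coefficients=final,
        column_names=tuple(design.column_names),
    )
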