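"""Repeated k-fold cross-validation of the concordance index.

The apparent c-index of a model fit and evaluated on the same patients
overstates generalizable discrimination; repeated k-fold CV quantifies
the gap.  Two summaries are reported: the mean held-out c-index
("average performance in cross-validation") and an optimism-corrected
c-index in the Harrell `validate` style, where per-fold optimism is the
training-fold apparent c-index minus the held-out c-index and

    corrected = apparent(full data) - mean(optimism).

A two-sided one-sample t-test of (apparent - held-out fold c-indices)
against zero provides the overfitting flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .concordance import cindex
from .coxph import fit_cox, risk_scores
from .datamodel_io import DesignMatrix, PatientTable, SurvivalOutcome, encode
from .errors import EstimationError
from .lasso_selection import select_features


@dataclass(frozen=True)
class CVResult:
    fold_cindices: np.ndarray  # shape (repeats, folds)
    mean_cv_cindex: float
    apparent_cindex: float
    corrected_cindex: float
    repeats: int
    folds: int
    overfit_flag: bool
    overfit_pvalue: float


def _subset_design(design: DesignMatrix, rows: np.ndarray) -> DesignMatrix:
    return DesignMatrix(
        design.column_names,
        design.matrix[rows],
        design.mapping,
        design.degenerate_columns,
    )


def _restrict_columns(design: DesignMatrix, names: tuple[str, ...]) -> DesignMatrix:
    idx = [i for i, c in enumerate(design.column_names) if c in set(names)]
    return DesignMatrix(
        tuple(design.column_names[i] for i in idx),
        design.matrix[:, idx],
        {design.column_names[i]: design.mapping[design.column_names[i]] for i in idx},
    )


def _apparent(design: DesignMatrix, outcome: SurvivalOutcome) -> float:
    fit = fit_cox(design, outcome)
    return cindex(risk_scores(fit, design), outcome).cindex


def cross_validate(
    table: PatientTable,
    folds: int = 10,
    repeats: int = 100,
    seed: int = 0,
    selection: bool = False,
    selection_folds: int = 10,
    selection_grid: np.ndarray | None = None,
) -> CVResult:
    """Repeated k-fold CV of a Cox model on the table's variables.

    With ``selection=True``, LASSO feature selection is re-run inside
    each training split (and once on the full data for the apparent
    model), so held-out folds never inform the selected set.
    """
    if folds < 2:
        raise EstimationError("need at least 2 folds")
    design = encode(table)
    outcome = table.outcome
    n = table.n_patients

    def fit_eval(train_design, train_outcome, sel_seed):
        """Returns (fit design restriction, fitted model)."""
        d = train_design
        if selection:
            sel = select_features(
                train_design, train_outcome, folds=selection_folds,
                seed=sel_seed, lambda_grid=selection_grid,
            )
            d = _restrict_columns(train_design, sel.selected)
        fit = fit_cox(d, train_outcome)
        return d.column_names, fit

    # apparent model on the full data
    app_cols, app_fit = fit_eval(design, outcome, seed)
    app_design = _restrict_columns(design, app_cols)
    apparent = cindex(risk_scores(app_fit, app_design), outcome).cindex

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    fold_c = np.zeros((repeats, folds))
    optimism = []
    for r in range(repeats):
        for attempt in range(10):
            perm = rng.permutation(n)
            parts = np.array_split(perm, folds)
            events_ok = all(outcome.event[part].sum() > 0 for part in parts) and all(
                outcome.event[np.setdiff1d(perm, part)].sum() > 0 for part in parts
            )
            if events_ok:
                break
        else:
            raise EstimationError("could not build folds with events in every training set")
        for k, held in enumerate(parts):
            train = np.setdiff1d(np.arange(n), held)
            tr_out = SurvivalOutcome(outcome.time[train], outcome.event[train])
            tr_design = _subset_design(design, train)
            cols, fit = fit_eval(tr_design, tr_out, seed + 1000 * r + k)
            tr_d = _restrict_columns(tr_design, cols)
            te_d = _restrict_columns(_subset_design(design, held), cols)
            te_out = SurvivalOutcome(outcome.time[held], outcome.event[held])
            held_c = cindex(risk_scores(fit, te_d), te_out).cindex
            train_c = cindex(risk_scores(fit, tr_d), tr_out).cindex
            fold_c[r, k] = held_c
            optimism.append(train_c - held_c)
    mean_cv = float(fold_c.mean())
    corrected = float(apparent - np.mean(optimism))
    diffs = apparent - fold_c.ravel()
    if np.allclose(diffs, 0.0):
        pval = 1.0
    else:
        pval = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    return CVResult(
        fold_cindices=fold_c,
        mean_cv_cindex=mean_cv,
        apparent_cindex=float(apparent),
        corrected_cindex=corrected,
        repeats=repeats,
        folds=folds,
        overfit_flag=bool(pval < 0.05),
        overfit_pvalue=pval,
    )
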