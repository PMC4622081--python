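"""Monte Carlo assessment of the information content of variable assemblages.

The procedure: permute each targeted predictor variable's values
independently across patients — destroying both predictor-outcome and
predictor-predictor correspondence — re-evaluate the model on every
randomised dataset, and compare the real model's performance statistic
against the resulting empirical null distribution.  The one-tailed
p-value is the proportion of randomised datasets whose statistic is
equal to or above the observed one.

Shuffling all variables measures the information content of the whole
assemblage; shuffling only a candidate subgroup inside a combined model
(:func:`added_value_test`) measures that subgroup's added value in the
context of the retained variables.  This differs from a conventional
permutation test, which shuffles only the outcome and therefore keeps
the correlation structure among predictors intact.

Any evaluator mapping a :class:`~survshuffle.datamodel_io.PatientTable`
to a scalar performance statistic can be plugged in; the shipped one is
Cox proportional hazards + Harrell's c-index, optionally with LASSO
feature selection and/or a cross-validation-corrected c-index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .concordance import cindex, cindex_from_mask, comparable_mask
from .coxph import BreslowData, _fit_prepared, fit_cox, risk_scores
from .datamodel_io import DesignMatrix, PatientTable, encode
from .errors import EstimationError, EvaluationFailure, PlanError

DEFAULT_N_PERMUTATIONS = 10_000
MAX_FAILURE_FRACTION = 0.05


@dataclass(frozen=True)
class ShufflePlan:
    """Which variables to shuffle, how many randomised datasets, and the
    master seed from which every per-draw, per-variable permutation is
    derived."""

    target_variables: tuple[str, ...]
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "target_variables", tuple(self.target_variables))
        if not self.target_variables:
            raise PlanError("shuffle plan must target at least one variable")
        if self.n_permutations < 1:
            raise PlanError("need at least one permutation")

    def validate_against(self, table: PatientTable) -> None:
        known = {v.name for v in table.variables}
        unknown = [v for v in self.target_variables if v not in known]
        if unknown:
            raise PlanError(f"plan targets unknown variables: {unknown}")


@dataclass(frozen=True)
class MCResult:
    observed_statistic: float
    permuted_statistics: np.ndarray
    pvalue: float
    pvalue_plus_one: float
    plan: ShufflePlan
    statistic_name: str
    n_failed: int = 0

    def formatted_pvalue(self) -> str:
        """Render the plain proportion, showing an exact zero as '< 1/N'."""
        n = self.permuted_statistics.shape[0]
        if self.pvalue == 0.0:
            return f"< {1.0 / n:g}"
        return f"{self.pvalue:g}"

    def histogram(self, bins: int = 50) -> dict:
        counts, edges = np.histogram(self.permuted_statistics, bins=bins)
        return {"bin_edges": edges.tolist(), "counts": counts.tolist(),
                "observed": self.observed_statistic}


def _child_permutation(n: int, seed: int, draw_index: int, var_index: int) -> np.ndarray:
    """Seeded permutation independent across (draw, variable) pairs, so
    results do not depend on evaluation order."""
    ss = np.random.SeedSequence((seed, draw_index, var_index))
    return np.random.default_rng(ss).permutation(n)


def shuffle_table(table: PatientTable, plan: ShufflePlan, draw_index: int) -> PatientTable:
    """One randomised dataset: each targeted variable's raw values are
    permuted by its own independent seeded permutation; everything else,
    including the outcome, is untouched.

    Shuffling acts on raw values before categorical encoding, so a
    categorical variable's indicator columns stay coherent.
    """
    plan.validate_against(table)
    values = table.values.copy()
    var_index = {v.name: i for i, v in enumerate(table.variables)}
    n = table.n_patients
    for name in plan.target_variables:
        perm = _child_permutation(n, plan.seed, draw_index, var_index[name])
        values[name] = values[name].to_numpy()[perm]
    return table.with_values(values)


class CoxCindexEvaluator:
    """The shipped evaluator: CPHR risk scores assessed by Harrell's c-index.

    Parameters
    ----------
    selection:
        Run LASSO feature selection before the (unpenalized) fit.  By
        default the selected set is FIXED from the unshuffled data and
        only the values are shuffled per draw; ``reselect_per_shuffle``
        repeats the selection on every randomised dataset instead (much
        slower, more conservative).
    cv_correct:
        Use the cross-validation-corrected c-index as the statistic
        instead of the apparent one.
    """

    def __init__(
        self,
        selection: bool = False,
        select_folds: int = 10,
        select_seed: int = 0,
        select_grid: np.ndarray | None = None,
        reselect_per_shuffle: bool = False,
        cv_correct: bool = False,
        cv_folds: int = 10,
        cv_repeats: int = 10,
        cv_seed: int = 0,
    ):
        self.selection = selection
        self.select_folds = select_folds
        self.select_seed = select_seed
        self.select_grid = select_grid
        self.reselect_per_shuffle = reselect_per_shuffle
        self.cv_correct = cv_correct
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.cv_seed = cv_seed

    @property
    def statistic_name(self) -> str:
        parts = ["cox"]
        if self.selection:
            parts.append("lasso")
        parts.append("corrected_cindex" if self.cv_correct else "cindex")
        return "_".join(parts)

    def _selected_columns(self, design: DesignMatrix, outcome) -> tuple[str, ...]:
        from .lasso_selection import select_features

        sel = select_features(design, outcome, folds=self.select_folds,
                              seed=self.select_seed, lambda_grid=self.select_grid)
        return sel.selected

    def __call__(self, table: PatientTable) -> float:
        from .crossval import cross_validate

        if self.cv_correct:
            # cross_validate re-runs selection inside each training split
            res = cross_validate(
                table, folds=self.cv_folds, repeats=self.cv_repeats,
                seed=self.cv_seed, selection=self.selection,
                selection_folds=self.select_folds,
                selection_grid=self.select_grid,
            )
            return res.corrected_cindex
        design = encode(table)
        if self.selection:
            cols = self._selected_columns(design, table.outcome)
            idx = [i for i, c in enumerate(design.column_names) if c in set(cols)]
            design = DesignMatrix(
                tuple(design.column_names[i] for i in idx),
                design.matrix[:, idx],
                {design.column_names[i]: design.mapping[design.column_names[i]]
                 for i in idx},
            )
        try:
            fit = fit_cox(design, table.outcome)
        except EstimationError as exc:
            raise EvaluationFailure(str(exc)) from exc
        return cindex(risk_scores(fit, design), table.outcome).cindex

    # -- fast path -----------------------------------------------------
    def prepare(self, table: PatientTable, plan: ShufflePlan):
        """Return a callable(draw_index) evaluating one randomised dataset
        without rebuilding tables, or None when no fast path applies.

        Bit-identical to ``self(shuffle_table(table, plan, k))``: the same
        per-(draw, variable) permutations are applied to the encoded
        columns of each targeted variable.
        """
        if self.cv_correct or (self.selection and self.reselect_per_shuffle):
            return None
        design = encode(table)
        outcome = table.outcome
        if self.selection:
            cols = self._selected_columns(design, outcome)
            idx = [i for i, c in enumerate(design.column_names) if c in set(cols)]
        else:
            idx = list(range(len(design.column_names)))
        names = tuple(design.column_names[i] for i in idx)
        X = design.matrix[:, idx]
        bd = BreslowData(X, outcome)
        earlier_sorted = comparable_mask(outcome)[np.ix_(bd.order, bd.order)]
        var_index = {v.name: i for i, v in enumerate(table.variables)}
        # per target variable: which columns of X (in idx space) it owns
        targets = []
        for name in plan.target_variables:
            owned = [k for k, i in enumerate(idx)
                     if design.mapping[design.column_names[i]] == name]
            targets.append((var_index[name], owned))
        n = table.n_patients

        def evaluate(draw_index: int) -> float:
            # Xp is in original row order; replace_matrix applies the
            # outcome sort, exactly as encode + BreslowData would.
            Xp = X.copy()
            for vi, owned in targets:
                if not owned:
                    continue
                perm = _child_permutation(n, plan.seed, draw_index, vi)
                Xp[:, owned] = X[np.ix_(perm, owned)]
            bdk = bd.replace_matrix(Xp)
            try:
                fit = _fit_prepared(bdk, names)
            except EstimationError as exc:
                raise EvaluationFailure(str(exc)) from exc
            scores_sorted = bdk.X @ fit.coefficients if fit.coefficients.size else np.zeros(n)
            return cindex_from_mask(scores_sorted, earlier_sorted)

        return evaluate


Evaluator = Callable[[PatientTable], float]


def mc_test(
    table: PatientTable,
    plan: ShufflePlan,
    evaluator: Evaluator,
    statistic_name: str | None = None,
    progress_every: int = 0,
) -> MCResult:
    """Monte Carlo information-content test for the targeted assemblage.

    Evaluator failures on randomised datasets (e.g. a diverging fit) are
    recorded and excluded, reducing the effective number of permutations;
    more than 5% failures aborts with an error because the null
    distribution would be unreliable.
    """
    plan.validate_against(table)
    observed = evaluator(table)
    fast = None
    prepare = getattr(evaluator, "prepare", None)
    if prepare is not None:
        fast = prepare(table, plan)
    stats_list: list[float] = []
    n_failed = 0
    for k in range(1, plan.n_permutations + 1):
        if progress_every and k % progress_every == 0:
            import sys

            print(f"  permutation {k}/{plan.n_permutations}", file=sys.stderr)
        try:
            if fast is not None:
                stat = fast(k)
            else:
                stat = evaluator(shuffle_table(table, plan, k))
        except EvaluationFailure:
            n_failed += 1
            continue
        stats_list.append(stat)
    if n_failed > MAX_FAILURE_FRACTION * plan.n_permutations:
        raise EstimationError(
            f"{n_failed}/{plan.n_permutations} evaluator failures (> "
            f"{MAX_FAILURE_FRACTION:.0%}); null distribution unreliable"
        )
    permuted = np.asarray(stats_list)
    n_eff = permuted.shape[0]
    count = int(np.sum(permuted >= observed))
    name = statistic_name or getattr(evaluator, "statistic_name", "statistic")
    return MCResult(
        observed_statistic=float(observed),
        permuted_statistics=permuted,
        pvalue=count / n_eff,
        pvalue_plus_one=(count + 1) / (n_eff + 1),
        plan=plan,
        statistic_name=name,
        n_failed=n_failed,
    )


def added_value_test(
    table: PatientTable,
    base_group: str,
    added_group: str,
    evaluator: Evaluator,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    plan: ShufflePlan | None = None,
) -> MCResult:
    """Shuffle only the added group inside the combined model.

    The model keeps both groups' variables; only the added group's values
    are randomised, so the p-value measures the added group's
    information content in the context of the base group.
    """
    base_vars = table.group_variables(base_group)
    added_vars = table.group_variables(added_group)
    if not base_vars:
        raise PlanError(f"no variables in base group {base_group!r}")
    if not added_vars:
        raise PlanError(f"no variables in added group {added_group!r}")
    combined = table.subset(base_vars + added_vars)
    if plan is None:
        plan = ShufflePlan(added_vars, n_permutations, seed)
    elif set(plan.target_variables) != set(added_vars):
        raise PlanError("plan must target exactly the added group's variables")
    return mc_test(combined, plan, evaluator)
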