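import numpy as np
import pytest

from survshuffle import (
    CoxCindexEvaluator,
    ShufflePlan,
    SurvivalOutcome,
    added_value_test,
    encode,
    mc_test,
    noise_table,
    shuffle_table,
)
from survshuffle.errors import EstimationError, EvaluationFailure, PlanError

from conftest import make_table


def test_shuffle_preserves_multiset_and_nontargets(mixed_table):
    plan = ShufflePlan(("m1", "stage"), n_permutations=5, seed=3)
    shuffled = shuffle_table(mixed_table, plan, draw_index=1)
    # targets: same values as a multiset, generally different order
    for name in ("m1",):
        assert sorted(shuffled.values[name]) == sorted(mixed_table.values[name])
        assert not shuffled.values[name].equals(mixed_table.values[name])
    assert sorted(shuffled.values["stage"]) == sorted(mixed_table.values["stage"])
    # non-targets and outcome untouched
    for name in ("age", "m2"):
        assert shuffled.values[name].equals(mixed_table.values[name])
    np.testing.assert_array_equal(shuffled.outcome.time, mixed_table.outcome.time)


def test_shuffle_is_reproducible_per_draw(mixed_table):
    plan = ShufflePlan(("m1", "m2"), n_permutations=5, seed=3)
    a = shuffle_table(mixed_table, plan, 2)
    b = shuffle_table(mixed_table, plan, 2)
    assert a.values.equals(b.values)
    c = shuffle_table(mixed_table, plan, 3)
    assert not c.values["m1"].equals(a.values["m1"])


def test_unknown_target_is_plan_error(mixed_table):
    plan = ShufflePlan(("nope",), n_permutations=2, seed=0)
    with pytest.raises(PlanError):
        shuffle_table(mixed_table, plan, 1)


def test_identical_columns_decorrelate_after_independent_shuffles():
    """Per-variable shuffling breaks the correspondence among variables:
    two originally identical columns average ~zero correlation."""
    rng = np.random.default_rng(0)
    n = 100
    x = rng.standard_normal(n)
    X = np.column_stack([x, x.copy()])
    out = SurvivalOutcome(np.arange(1.0, n + 1), np.ones(n, int))
    table = make_table(X, out)
    plan = ShufflePlan(("v00", "v01"), n_permutations=1000, seed=5)
    corrs = []
    for k in range(1, 1001):
        s = shuffle_table(table, plan, k)
        corrs.append(np.corrcoef(s.values["v00"], s.values["v01"])[0, 1])
    assert abs(np.mean(corrs)) < 0.02


def test_constant_evaluator_gives_pvalue_one(mixed_table):
    plan = ShufflePlan(("m1",), n_permutations=20, seed=1)
    res = mc_test(mixed_table, plan, lambda t: 0.42, statistic_name="const")
    assert res.pvalue == 1.0
    assert res.pvalue_plus_one == 21 / 21
    assert res.observed_statistic == 0.42


def test_observed_above_all_permuted_formats_as_less_than_one_over_n(mixed_table):
    reference = mixed_table.values.copy()

    def detector(table):
        return 1.0 if table.values.equals(reference) else 0.0

    plan = ShufflePlan(("m1", "m2"), n_permutations=10, seed=2)
    res = mc_test(mixed_table, plan, detector, statistic_name="identity")
    assert res.pvalue == 0.0
    assert res.pvalue_plus_one == pytest.approx(1 / 11)
    assert res.formatted_pvalue() == "< 0.1"


def test_mc_result_reproducible_bitwise():
    table = noise_table(80, 4, seed=10)
    plan = ShufflePlan(tuple(v.name for v in table.variables), 25, seed=9)
    a = mc_test(table, plan, CoxCindexEvaluator())
    b = mc_test(table, plan, CoxCindexEvaluator())
    assert a.observed_statistic == b.observed_statistic
    np.testing.assert_array_equal(a.permuted_statistics, b.permuted_statistics)
    assert a.pvalue == b.pvalue


def test_fast_path_identical_to_table_level_shuffling(mixed_table):
    """The design-level fast path must reproduce the generic
    shuffle-then-encode route bit for bit, including for categorical
    targets whose indicator columns must move together."""
    plan = ShufflePlan(("stage", "m1"), n_permutations=15, seed=4)
    ev = CoxCindexEvaluator()
    fast = mc_test(mixed_table, plan, ev)

    class NoFastPath:
        def __call__(self, table):
            return ev(table)

    slow = mc_test(mixed_table, plan, NoFastPath(), statistic_name=ev.statistic_name)
    assert fast.observed_statistic == slow.observed_statistic
    np.testing.assert_array_equal(fast.permuted_statistics, slow.permuted_statistics)


def test_evaluator_failures_excluded_and_counted(mixed_table):
    calls = {"k": -1}

    def flaky(table):
        calls["k"] += 1
        if calls["k"] in (3, 7):  # two of the shuffled draws fail
            raise EvaluationFailure("no convergence")
        return float(calls["k"])

    plan = ShufflePlan(("m1",), n_permutations=50, seed=0)
    res = mc_test(mixed_table, plan, flaky, statistic_name="flaky")
    assert res.n_failed == 2
    assert res.permuted_statistics.shape[0] == 48
    # plain p-value uses the reduced N
    assert res.pvalue == np.mean(res.permuted_statistics >= res.observed_statistic)


def test_excessive_failures_abort(mixed_table):
    calls = {"n": 0}

    def broken(table):
        calls["n"] += 1
        if calls["n"] > 1:
            raise EvaluationFailure("boom")
        return 0.5

    plan = ShufflePlan(("m1",), n_permutations=30, seed=0)
    with pytest.raises(EstimationError, match="unreliable"):
        mc_test(mixed_table, plan, broken)


def test_added_value_requires_matching_plan(mixed_table):
    ev = CoxCindexEvaluator()
    with pytest.raises(PlanError):
        added_value_test(mixed_table, "clinical", "absent", ev, n_permutations=5)
    bad_plan = ShufflePlan(("age",), 5, 0)
    with pytest.raises(PlanError):
        added_value_test(
            mixed_table, "clinical", "molecular", ev, plan=bad_plan
        )


def test_added_value_shuffles_only_added_group(mixed_table):
    ev = CoxCindexEvaluator()
    res = added_value_test(mixed_table, "clinical", "molecular", ev,
                           n_permutations=10, seed=1)
    assert set(res.plan.target_variables) == {"m1", "m2"}
    assert res.permuted_statistics.shape[0] == 10


def test_per_variable_shuffle_differs_from_outcome_permutation():
    """On correlated predictors that jointly carry signal, the null built
    by independent per-variable shuffling has a different mean c-index
    than the conventional outcome-permutation null, which preserves the
    predictor correlation structure."""
    rng = np.random.default_rng(123)
    n = 80
    Z = rng.standard_normal((n, 3))
    # three predictors, each entered twice (perfectly correlated pairs):
    # outcome permutation preserves the duplication (rank 3), while
    # independent per-variable shuffling breaks it (rank 6), so the two
    # null c-index distributions separate
    X = np.repeat(Z, 2, axis=1)
    eta = 0.7 * Z[:, 0] - 0.7 * Z[:, 1]
    time = rng.exponential(np.exp(-eta)) + 1e-3
    out = SurvivalOutcome(time, np.ones(n, int))
    table = make_table(X, out)
    ev = CoxCindexEvaluator()
    plan = ShufflePlan(tuple(v.name for v in table.variables),
                       n_permutations=150, seed=11)
    shuffle_null = mc_test(table, plan, ev).permuted_statistics

    perm_rng = np.random.default_rng(99)
    outcome_null = []
    for _ in range(150):
        perm = perm_rng.permutation(n)
        out2 = SurvivalOutcome(time[perm], np.ones(n, int))
        t2 = type(table)(table.patient_ids, out2, table.variables, table.values)
        outcome_null.append(ev(t2))
    outcome_null = np.asarray(outcome_null)
    from scipy import stats

    pv = stats.ttest_ind(shuffle_null, outcome_null, equal_var=False).pvalue
    assert pv < 0.01  # detectably different null distributions
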