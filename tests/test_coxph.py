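import numpy as np
import pytest
from scipy import optimize, stats

from survshuffle import DesignMatrix, SurvivalOutcome, fit_cox, risk_scores, schoenfeld_test
from survshuffle.coxph import BreslowData, breslow_loglik
from survshuffle.errors import DivergenceError, EstimationError

from conftest import random_survival_instance


def null_loglik_by_hand(time, event):
    """Breslow log-likelihood at beta = 0: sum over events of -log |risk set|,
    risk set = patients with time >= the event's time."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            ll -= np.log(np.sum(time >= time[i]))
    return ll


def test_null_loglik_closed_form(rng):
    outcome, design = random_survival_instance(rng, 25, p=2, tie_times=True)
    fit = fit_cox(design, outcome)
    assert fit.loglik_null == pytest.approx(
        null_loglik_by_hand(outcome.time, outcome.event), abs=1e-10
    )
    assert fit.loglik_final >= fit.loglik_null - 1e-12


def test_constant_column_keeps_zero_coefficient(rng):
    outcome, design = random_survival_instance(rng, 30, p=1)
    X = np.column_stack([design.matrix[:, 0], np.full(30, 3.0)])
    d2 = DesignMatrix(("x0", "const"), X, {"x0": "x0", "const": "const"})
    fit = fit_cox(d2, outcome)
    assert fit.ridged  # singular information flagged, stabilized
    assert abs(fit.coefficients[1]) < 1e-6


@pytest.mark.parametrize("seed", range(10))
def test_matches_derivative_free_oracle(seed):
    """Newton solution equals a Nelder-Mead maximization of the same
    Breslow partial log-likelihood (small n, mixed censoring, ties)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(15, 41))
    p = int(rng.integers(1, 4))
    outcome, design = random_survival_instance(rng, n, p=p, tie_times=bool(seed % 2))
    fit = fit_cox(design, outcome)
    bd = BreslowData(design.matrix, outcome)
    res = optimize.minimize(
        lambda b: -breslow_loglik(bd, b),
        np.zeros(p),
        method="Nelder-Mead",
        options=dict(xatol=1e-9, fatol=1e-13, maxiter=20000, maxfev=20000),
    )
    assert np.max(np.abs(res.x - fit.coefficients)) < 1e-5
    assert fit.loglik_final == pytest.approx(-res.fun, abs=1e-8)


def test_matches_lifelines_on_tie_free_data(rng):
    # lifelines implements Efron tie handling only; with no tied event
    # times Efron and Breslow coincide, giving an independent cross-check
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    outcome, design = random_survival_instance(rng, 80, p=3, tie_times=False)
    fit = fit_cox(design, outcome)
    df = pd.DataFrame(design.matrix, columns=design.column_names)
    df["T"], df["E"] = outcome.time, outcome.event
    cph = lifelines.CoxPHFitter()
    cph.fit(df, "T", "E")
    np.testing.assert_allclose(cph.params_.values, fit.coefficients, atol=1e-6)
    np.testing.assert_allclose(
        cph.standard_errors_.values, fit.standard_errors, atol=1e-5
    )


def test_translation_invariance(rng):
    outcome, design = random_survival_instance(rng, 40, p=2)
    fit1 = fit_cox(design, outcome)
    shifted = DesignMatrix(
        design.column_names, design.matrix + np.array([5.0, -3.0]), design.mapping
    )
    fit2 = fit_cox(shifted, outcome)
    np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, atol=1e-7)
    assert (fit1.loglik_final - fit1.loglik_null) == pytest.approx(
        fit2.loglik_final - fit2.loglik_null, abs=1e-8
    )


def test_monotone_likelihood_raises_divergence_naming_column():
    n = 20
    time = np.arange(1.0, n + 1)
    event = np.ones(n, int)
    x = -time  # perfectly orders the events: likelihood is monotone in beta
    design = DesignMatrix(("sep",), x[:, None], {"sep": "sep"})
    with pytest.raises(DivergenceError, match="sep"):
        fit_cox(design, SurvivalOutcome(time, event))


def test_no_events_is_estimation_error():
    design = DesignMatrix(("x",), np.ones((5, 1)), {"x": "x"})
    with pytest.raises(EstimationError):
        fit_cox(design, SurvivalOutcome(np.arange(1.0, 6), np.zeros(5, int)))


def test_risk_scores_identity_and_ordering(rng):
    import dataclasses

    outcome, design = random_survival_instance(rng, 30, p=1)
    fit = fit_cox(design, outcome)
    # beta = 0 -> all scores zero
    zero_fit = dataclasses.replace(fit, coefficients=np.zeros(1))
    np.testing.assert_array_equal(risk_scores(zero_fit, design), 0.0)
    # single column with beta = 1 -> scores equal the column
    one_fit = dataclasses.replace(fit, coefficients=np.ones(1))
    np.testing.assert_array_equal(risk_scores(one_fit, design), design.matrix[:, 0])
    with pytest.raises(EstimationError):
        risk_scores(fit, DesignMatrix(("a", "b"), np.ones((30, 2)), {"a": "a", "b": "b"}))


def test_risk_scores_recover_true_ordering():
    """With a strong known effect, fitted scores rank patients like the
    true linear predictor."""
    from survshuffle import encode, noise_table

    table = noise_table(500, 2, seed=42, informative_beta={"v00": 1.0, "v01": -0.7})
    design = encode(table)
    fit = fit_cox(design, table.outcome)
    true_eta = design.matrix @ np.array([1.0, -0.7])
    rho = stats.spearmanr(risk_scores(fit, design), true_eta).statistic
    assert rho > 0.9


def test_schoenfeld_residuals_sum_to_zero_at_mle(rng):
    outcome, design = random_survival_instance(rng, 60, p=2)
    fit = fit_cox(design, outcome)
    diag = schoenfeld_test(fit, design, outcome)
    assert diag.residuals.shape[0] == outcome.n_events
    np.testing.assert_allclose(diag.residuals.sum(axis=0), 0.0, atol=1e-6)


def test_schoenfeld_calibration_under_proportional_hazards():
    """Global p-value roughly uniform when the data satisfy PH."""
    from survshuffle import encode, noise_table

    pvals = []
    for r in range(100):
        table = noise_table(100, 2, seed=7000 + r, informative_beta={"v00": 0.5})
        design = encode(table)
        fit = fit_cox(design, table.outcome)
        pvals.append(schoenfeld_test(fit, design, table.outcome).global_pvalue)
    pvals = np.asarray(pvals)
    assert 0.35 < pvals.mean() < 0.65
    # no gross departure from uniformity
    d = stats.kstest(pvals, "uniform").statistic
    assert d < 0.2


def test_schoenfeld_detects_sign_reversing_effect():
    """A covariate whose effect reverses over time violates PH and should
    yield small per-column p-values in most replicates."""
    hits = 0
    reps = 30
    for r in range(reps):
        rng = np.random.default_rng(9000 + r)
        n = 150
        x = rng.standard_normal(n)
        base = rng.exponential(1.0, n)
        med = np.median(base)
        # early times pulled earlier for high x, late times pulled later
        time = np.where(base < med, base * np.exp(-x), base * np.exp(x)) + 1e-3
        outcome = SurvivalOutcome(time, np.ones(n, int))
        design = DesignMatrix(("x",), x[:, None], {"x": "x"})
        fit = fit_cox(design, outcome)
        diag = schoenfeld_test(fit, design, outcome)
        hits += diag.per_column_pvalue[0] < 0.05
    assert hits / reps > 0.5


def test_schoenfeld_needs_three_events(rng):
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([1, 1, 0, 0])
    design = DesignMatrix(("x",), rng.normal(size=(4, 1)), {"x": "x"})
    outcome = SurvivalOutcome(time, event)
    fit = fit_cox(design, outcome)
    with pytest.raises(EstimationError):
        schoenfeld_test(fit, design, outcome)
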