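import numpy as np
import pandas as pd
import pytest

from survshuffle import (
    DesignMatrix,
    PatientTable,
    SurvivalOutcome,
    VariableSpec,
)


def random_survival_instance(rng, n, p=0, censor_frac=0.3, tie_times=False):
    """A small random censored dataset for oracle comparisons.

    With ``tie_times`` the times are drawn from a coarse integer grid so
    tied event/censoring times occur frequently.
    """
    if tie_times:
        time = rng.integers(1, max(3, n // 2), size=n).astype(float)
    else:
        time = rng.exponential(1.0, size=n) + 1e-3
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[rng.integers(0, n)] = 1
    outcome = SurvivalOutcome(time, event)
    if p == 0:
        return outcome
    X = rng.standard_normal((n, p))
    names = tuple(f"x{j}" for j in range(p))
    design = DesignMatrix(names, X, {nm: nm for nm in names})
    return outcome, design


def make_table(X, outcome, group="g"):
    """Wrap a numeric matrix as a PatientTable of continuous variables."""
    n, p = X.shape
    names = [f"v{j:02d}" for j in range(p)]
    specs = tuple(VariableSpec(nm, "continuous", group=group) for nm in names)
    values = pd.DataFrame({nm: X[:, j] for j, nm in enumerate(names)})
    ids = tuple(f"P{i:04d}" for i in range(n))
    return PatientTable(ids, outcome, specs, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def mixed_table(rng):
    """Small table with continuous and categorical variables in two groups."""
    n = 60
    stage = rng.choice(["I", "II", "III"], size=n, p=[0.3, 0.3, 0.4])
    specs = (
        VariableSpec("age", "continuous", group="clinical"),
        VariableSpec("stage", "categorical", ("I", "II", "III"), "clinical"),
        VariableSpec("m1", "continuous", group="molecular"),
        VariableSpec("m2", "continuous", group="molecular"),
    )
    values = pd.DataFrame(
        {
            "age": rng.normal(60, 10, n),
            "stage": stage,
            "m1": rng.normal(100, 30, n),
            "m2": rng.normal(100, 30, n),
        }
    )
    eta = 0.6 * (stage == "III").astype(float)
    time = rng.exponential(500 * np.exp(-eta)) + 1.0
    event = (rng.uniform(size=n) > 0.3).astype(int)
    ids = tuple(f"P{i:04d}" for i in range(n))
    return PatientTable(ids, SurvivalOutcome(time, event), specs, values)
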