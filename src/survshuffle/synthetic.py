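"""Synthetic right-censored survival data with known Cox effects.

The generator emulates the structure of an ovarian-cancer cohort of 339
patients: five clinicopathological inputs (age in days, both continuous
and stratified at 50 years; histopathology with six levels; FIGO-style
stage with four levels; chemotherapy regimen with two levels) and twenty
proteomic measures on the automated-quantitative-immunofluorescence
(AQUA) intensity scale of 0-255, each attached to a subcellular
compartment (nucleus or cytoplasm).

Event times follow a Weibull proportional hazards model

    S(t | x) = exp( -(t / scale)^shape * exp(x' beta_true) )

sampled by inverse transform; censoring times are exponential with a
rate calibrated so the realized censored fraction matches the requested
target.  ``beta_true`` is the generator's ground truth, which recovery
and calibration tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel_io import (
    CATEGORICAL,
    CONTINUOUS,
    PatientTable,
    SurvivalOutcome,
    VariableSpec,
    encode,
)
from .errors import ValidationError

DAYS_PER_YEAR = 365.25

_NUCLEAR_ONLY = (
    "pERK",
    "pBetaCatenin",
    "pSTAT3_Ser727",
    "pSTAT3_Ser705",
    "pNFkB",
    "pRB",
    "pH2AX",
    "pBRCA1",
    "p_p53",
    "Ki67",
    "pHH3",
    "cleaved_caspase3",
    "WT1",
)
_CYTOPLASM_ONLY = ("Snail", "Slug", "E-cadherin")
_BOTH_COMPARTMENTS = ("ERbeta1", "ERbeta2")

HISTOPATHOLOGY_LEVELS = (
    "papillary serous",
    "clear cell",
    "endometrioid",
    "mixed histology",
    "mucinous",
    "adenocarcinoma",
)
STAGE_LEVELS = ("stage 1", "stage 2", "stage 3", "stage 4")
REGIMEN_LEVELS = ("platinum", "platinum + taxane")
AGE_STRATUM_LEVELS = ("<50 years", ">50 years")


def study_schema(age_form: str = "both") -> list[VariableSpec]:
    """The fixed cohort schema: 5 clinicopathological + 20 proteomic variables.

    By default age enters twice, as a continuous variable (in days) and
    as a binary stratum at 50 years; ``age_form`` of ``"continuous"`` or
    ``"stratified"`` restricts it to one form.  Proteomic names carry
    their subcellular compartment as a suffix.
    """
    if age_form not in ("both", "continuous", "stratified"):
        raise ValidationError("age_form must be 'both', 'continuous' or 'stratified'")
    clin = []
    if age_form in ("both", "continuous"):
        clin.append(VariableSpec("age_days", CONTINUOUS, group="clinicopathological"))
    if age_form in ("both", "stratified"):
        clin.append(
            VariableSpec("age_stratum", CATEGORICAL, AGE_STRATUM_LEVELS,
                         "clinicopathological")
        )
    clin += [
        VariableSpec("histopathology", CATEGORICAL, HISTOPATHOLOGY_LEVELS, "clinicopathological"),
        VariableSpec("stage", CATEGORICAL, STAGE_LEVELS, "clinicopathological"),
        VariableSpec("regimen", CATEGORICAL, REGIMEN_LEVELS, "clinicopathological"),
    ]
    prot = [
        VariableSpec(f"{name}_nucleus", CONTINUOUS, group="proteomic")
        for name in _NUCLEAR_ONLY
    ]
    prot += [
        VariableSpec(f"{name}_cytoplasm", CONTINUOUS, group="proteomic")
        for name in _CYTOPLASM_ONLY
    ]
    for name in _BOTH_COMPARTMENTS:
        prot.append(VariableSpec(f"{name}_nucleus", CONTINUOUS, group="proteomic"))
        prot.append(VariableSpec(f"{name}_cytoplasm", CONTINUOUS, group="proteomic"))
    return clin + prot


#: Default ground-truth effects (per design column, log hazard ratio).
#: Clinicopathological variables carry most of the prognostic signal
#: (advanced stage and unfavourable histology increase hazard); a handful
#: of proteomic markers carry modest per-unit effects with signs matching
#: their reported prognostic direction (E-cadherin and cleaved caspase-3
#: protective, pH2AX and WT1 adverse, nuclear beta-catenin protective).
DEFAULT_TRUE_BETA: dict[str, float] = {
    "age_days": 0.018 / DAYS_PER_YEAR,
    "age_stratum[>50 years]": 0.15,
    "histopathology[clear cell]": 0.5,
    "histopathology[endometrioid]": -0.2,
    "histopathology[mixed histology]": 0.2,
    "histopathology[mucinous]": 0.4,
    "histopathology[adenocarcinoma]": 0.1,
    "stage[stage 2]": 0.35,
    "stage[stage 3]": 0.8,
    "stage[stage 4]": 1.2,
    "regimen[platinum + taxane]": -0.25,
    "E-cadherin_cytoplasm": -0.008,
    "cleaved_caspase3_nucleus": -0.006,
    "pH2AX_nucleus": 0.005,
    "WT1_nucleus": 0.005,
    "pBetaCatenin_nucleus": -0.004,
}

_HISTO_PROBS = (0.55, 0.08, 0.12, 0.08, 0.04, 0.13)
_STAGE_PROBS = (0.12, 0.10, 0.58, 0.20)
_REGIMEN_PROBS = (0.30, 0.70)


@dataclass(frozen=True)
class GeneratorConfig:
    """Simulation settings; defaults emulate the cohort structure above."""

    n_patients: int = 339
    schema: tuple[VariableSpec, ...] = field(default_factory=lambda: tuple(study_schema()))
    true_beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    baseline_shape: float = 1.2
    baseline_scale: float = 733.0  # days; median event time ~540 d at eta = 0
    censoring_rate: float = 0.30
    correlation: np.ndarray | None = None  # optional, continuous proteomic block
    aqua_mean: float = 100.0
    aqua_sd: float = 40.0
    outcome: str = "pfs"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.censoring_rate < 1.0):
            raise ValidationError("censoring_rate must lie in (0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValidationError("Weibull shape and scale must be positive")
        if self.outcome not in ("pfs", "os"):
            raise ValidationError("outcome must be 'pfs' or 'os'")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape[0] != c.shape[1] or not np.allclose(c, c.T):
                raise ValidationError("correlation matrix must be square and symmetric")
            if np.linalg.eigvalsh(c).min() <= 0:
                raise ValidationError("correlation matrix must be positive-definite")
            object.__setattr__(self, "correlation", c)


def _truncnorm_aqua(rng, n, mean, sd):
    a, b = (0.0 - mean) / sd, (255.0 - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=n))


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    cols: dict[str, np.ndarray] = {}
    cont_specs = [s for s in config.schema if s.kind == CONTINUOUS]
    prot_cont = [s for s in cont_specs if s.group == "proteomic"]
    # Gaussian copula for the proteomic block when a correlation is given
    copula: dict[str, np.ndarray] = {}
    if config.correlation is not None and prot_cont:
        k = config.correlation.shape[0]
        if k != len(prot_cont):
            raise ValidationError(
                f"correlation is {k}x{k} but there are {len(prot_cont)} "
                "continuous proteomic variables"
            )
        L = np.linalg.cholesky(config.correlation)
        z = rng.standard_normal((n, k)) @ L.T
        u = stats.norm.cdf(z)
        a = (0.0 - config.aqua_mean) / config.aqua_sd
        b = (255.0 - config.aqua_mean) / config.aqua_sd
        dist = stats.truncnorm(a, b, loc=config.aqua_mean, scale=config.aqua_sd)
        for j, spec in enumerate(prot_cont):
            copula[spec.name] = dist.ppf(u[:, j])
    age_years = None
    for spec in config.schema:
        if spec.kind == CONTINUOUS:
            if spec.name == "age_days":
                lo, hi = (30 - 60) / 10, (88 - 60) / 10
                age_years = stats.truncnorm(lo, hi, loc=60, scale=10).ppf(rng.uniform(size=n))
                cols[spec.name] = age_years * DAYS_PER_YEAR
            elif spec.name in copula:
                cols[spec.name] = copula[spec.name]
            else:
                cols[spec.name] = _truncnorm_aqua(rng, n, config.aqua_mean, config.aqua_sd)
        else:
            if spec.name == "age_stratum" and age_years is not None:
                cols[spec.name] = np.where(
                    age_years < 50, AGE_STRATUM_LEVELS[0], AGE_STRATUM_LEVELS[1]
                )
            else:
                probs = {
                    "histopathology": _HISTO_PROBS,
                    "stage": _STAGE_PROBS,
                    "regimen": _REGIMEN_PROBS,
                }.get(spec.name)
                if probs is None or len(probs) != len(spec.levels):
                    probs = np.full(len(spec.levels), 1.0 / len(spec.levels))
                cols[spec.name] = rng.choice(spec.levels, size=n, p=np.asarray(probs))
    return pd.DataFrame({s.name: cols[s.name] for s in config.schema})


def sample_event_times(
    rng: np.random.Generator, eta: np.ndarray, shape: float, scale: float
) -> np.ndarray:
    """Weibull proportional-hazards event times by inverse transform."""
    u = rng.uniform(size=eta.shape[0])
    return scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / shape)


def _calibrated_censoring(
    rng: np.random.Generator, t_event: np.ndarray, target: float, max_tries: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential censoring with rate solved so that the conditional
    expected censored fraction, mean_i P(C < t_i), equals the target;
    redraw (recalibrating) until the realized fraction is within 0.05."""

    def expected_censored(rate):
        return float(np.mean(-np.expm1(-rate * t_event))) - target

    lo, hi = 1e-12, 1.0
    while expected_censored(hi) < 0 and hi < 1e8:
        hi *= 10
    if expected_censored(hi) < 0:
        raise ValidationError("censoring target infeasible for these event times")
    rate = optimize.brentq(expected_censored, lo, hi)
    for _ in range(max_tries):
        c = rng.exponential(scale=1.0 / rate, size=t_event.shape[0])
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
        realized = 1.0 - event.mean()
        if abs(realized - target) <= 0.05:
            return time, event
    raise ValidationError(
        f"could not realize censoring within +/-0.05 of {target} in {max_tries} draws"
    )


def generate(config: GeneratorConfig) -> PatientTable:
    """Draw one synthetic cohort under the configured ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    values = _draw_covariates(config, rng)
    ids = tuple(f"P{i:04d}" for i in range(config.n_patients))
    # dummy outcome for encoding only
    table0 = PatientTable(
        ids,
        SurvivalOutcome(np.ones(config.n_patients), np.ones(config.n_patients, dtype=int)),
        tuple(config.schema),
        values,
    )
    design = encode(table0)
    beta = np.array([config.true_beta.get(c, 0.0) for c in design.column_names])
    eta = design.matrix @ beta
    eta = eta - eta.mean()  # centre so baseline scale keeps its interpretation
    t_pfs = sample_event_times(rng, eta, config.baseline_shape, config.baseline_scale)
    if config.outcome == "os":
        t_latent = t_pfs + rng.exponential(scale=400.0, size=config.n_patients)
    else:
        t_latent = t_pfs
    time, event = _calibrated_censoring(rng, t_latent, config.censoring_rate)
    outcome = SurvivalOutcome(time, event)
    return PatientTable(ids, outcome, tuple(config.schema), values)


def generate_joint(config: GeneratorConfig) -> tuple[PatientTable, PatientTable]:
    """Draw one cohort carrying both a PFS-like and an OS-like outcome.

    OS latent event time = PFS latent time + a positive gap, and the OS
    censoring time = PFS censoring time + an independent positive gap, so
    the observed OS time is >= the observed PFS time for every patient.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    values = _draw_covariates(config, rng)
    n = config.n_patients
    ids = tuple(f"P{i:04d}" for i in range(n))
    table0 = PatientTable(
        ids,
        SurvivalOutcome(np.ones(n), np.ones(n, dtype=int)),
        tuple(config.schema),
        values,
    )
    design = encode(table0)
    beta = np.array([config.true_beta.get(c, 0.0) for c in design.column_names])
    eta = design.matrix @ beta
    eta = eta - eta.mean()
    t_pfs = sample_event_times(rng, eta, config.baseline_shape, config.baseline_scale)
    t_os = t_pfs + rng.exponential(scale=400.0, size=n)

    def expected_censored(rate):
        return float(np.mean(-np.expm1(-rate * t_pfs))) - config.censoring_rate

    hi = 1.0
    while expected_censored(hi) < 0 and hi < 1e8:
        hi *= 10
    rate = optimize.brentq(expected_censored, 1e-12, hi)
    c_pfs = rng.exponential(scale=1.0 / rate, size=n)
    c_os = c_pfs + rng.exponential(scale=400.0, size=n)
    pfs = SurvivalOutcome(np.minimum(t_pfs, c_pfs), (t_pfs <= c_pfs).astype(int))
    os_ = SurvivalOutcome(np.minimum(t_os, c_os), (t_os <= c_os).astype(int))
    return (
        PatientTable(ids, pfs, tuple(config.schema), values),
        PatientTable(ids, os_, tuple(config.schema), values),
    )


def noise_table(
    n_patients: int,
    n_variables: int,
    censoring_rate: float = 0.30,
    seed: int = 0,
    group: str = "proteomic",
    informative_beta: Mapping[str, float] | None = None,
    baseline_shape: float = 1.2,
    baseline_scale: float = 733.0,
) -> PatientTable:
    """Convenience cohort of standard-normal continuous covariates, all
    noise unless ``informative_beta`` assigns nonzero log hazard ratios
    by variable name.

    Used throughout calibration and power studies: variables are named
    ``v00, v01, ...``, carry a single group label and have unit variance,
    so an effect of 1 means a hazard ratio of e per standard deviation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    names = [f"v{j:02d}" for j in range(n_variables)]
    schema = tuple(VariableSpec(name, CONTINUOUS, group=group) for name in names)
    X = rng.standard_normal((n_patients, n_variables))
    beta = np.array([(informative_beta or {}).get(name, 0.0) for name in names])
    eta = X @ beta
    t_event = sample_event_times(rng, eta, baseline_shape, baseline_scale)
    time, event = _calibrated_censoring(rng, t_event, censoring_rate)
    ids = tuple(f"P{i:04d}" for i in range(n_patients))
    values = pd.DataFrame({name: X[:, j] for j, name in enumerate(names)})
    return PatientTable(ids, SurvivalOutcome(time, event), schema, values)
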