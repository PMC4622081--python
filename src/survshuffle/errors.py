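"""Exception hierarchy shared across the package."""


class SurvShuffleError(Exception):
    """Base class for all package errors."""


class SchemaError(SurvShuffleError):
    """A dataset does not match its declared variable schema."""


class ValidationError(SurvShuffleError):
    """A value violates an invariant (non-positive time, unknown level, ...)."""


class EstimationError(SurvShuffleError):
    """A model cannot be estimated on the given data (e.g. no events)."""


class DivergenceError(EstimationError):
    """Monotone partial likelihood: a coefficient diverged past the bound."""

    def __init__(self, column: str, bound: float):
        self.column = column
        self.bound = bound
        super().__init__(
            f"coefficient for column {column!r} diverged past |beta| > {bound}; "
            "the column may perfectly separate the event ordering"
        )


class ConvergenceError(EstimationError):
    """Newton iterations exhausted without meeting the score tolerance."""


class EvaluationFailure(SurvShuffleError):
    """An evaluator failed on one randomised dataset (recorded, not fatal)."""


class PlanError(SurvShuffleError):
    """A shuffle plan references unknown variables or is otherwise invalid."""
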