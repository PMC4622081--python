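"""Harrell's concordance index for right-censored outcomes.

A pair of patients is comparable when the observed ordering of their
outcomes is known despite censoring: the patient with the smaller
observed time must have had the event.  Pairs of two censored patients
are incomparable, as are pairs with tied times where both had the event;
a tied time with exactly one event counts the event patient as the
earlier one.  The pair is concordant when the earlier patient carries
the higher risk score; tied scores contribute 1/2.

``cindex`` enumerates all pairs directly (O(n^2)); at the cohort sizes
this package targets (hundreds of patients) that is both exact and fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel_io import SurvivalOutcome
from .errors import EstimationError


@dataclass(frozen=True)
class ConcordanceResult:
    cindex: float
    concordant: int
    discordant: int
    tied_risk: int
    comparable_pairs: int


def comparable_mask(outcome: SurvivalOutcome) -> np.ndarray:
    """Boolean matrix: entry (i, j) is True when i is the *earlier* member
    of a comparable pair with j.  Each comparable unordered pair appears
    exactly once."""
    t = outcome.time
    d = outcome.event.astype(bool)
    ti, tj = t[:, None], t[None, :]
    di, dj = d[:, None], d[None, :]
    return ((ti < tj) & di) | ((ti == tj) & di & ~dj)


def cindex_from_mask(scores: np.ndarray, earlier: np.ndarray) -> float:
    """Concordance value given a precomputed comparability mask (fast path
    for repeated evaluation against a fixed outcome)."""
    diff = scores[:, None] - scores[None, :]
    total = int(earlier.sum())
    if total == 0:
        raise EstimationError("no comparable pairs; c-index undefined")
    concordant = int((diff > 0)[earlier].sum())
    tied = int((diff == 0)[earlier].sum())
    return (concordant + 0.5 * tied) / total


def cindex(scores: np.ndarray, outcome: SurvivalOutcome) -> ConcordanceResult:
    """Harrell's c-index of risk scores against a right-censored outcome."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(outcome):
        raise EstimationError("scores and outcome must have equal length")
    earlier = comparable_mask(outcome)
    total = int(earlier.sum())
    if total == 0:
        raise EstimationError("no comparable pairs; c-index undefined")
    diff = scores[:, None] - scores[None, :]
    concordant = int((diff > 0)[earlier].sum())
    tied = int((diff == 0)[earlier].sum())
    discordant = total - concordant - tied
    return ConcordanceResult(
        cindex=(concordant + 0.5 * tied) / total,
        concordant=concordant,
        discordant=discordant,
        tied_risk=tied,
        comparable_pairs=total,
    )
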