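"""Probability/rate conversion chain for cohort-derived transition inputs.

Decision models that run in discrete cycles need per-cycle transition
probabilities, but what a retrospective cohort yields directly is a naive
cumulative proportion: the fraction of patients with the event over the
observation window.  Under a constant-hazard (exponential) assumption the
three quantities interconvert:

1. cumulative probability over ``t`` years:  ``P = n_event / n_total``
2. constant yearly rate:                     ``r = -ln(1 - P) / t``
3. probability over a fixed span ``t'``:     ``P' = 1 - exp(-r * t')``

Applying (1)->(2)->(3) with ``t' = 1/12`` year turns cohort counts into
monthly transition probabilities.  The proportion in step (1) deliberately
ignores censoring and competing risks — it is the estimator real-world
costing studies actually use — and the resulting bias is characterised by
the synthetic-cohort module, not corrected here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import CountInconsistencyError, InfiniteRateError, InvalidCohortError

__all__ = [
    "CohortCounts",
    "EventProbability",
    "EventRate",
    "MonthlyTransitionProbabilities",
    "cumulative_event_probability",
    "rate_from_probability",
    "probability_over_time",
    "monthly_transition_probabilities",
]

MONTHS_PER_YEAR = 12
#: One model month expressed in years. The model is defined on a monthly
#: grid, so a month is exactly 1/12 year (not 30/365) to keep cycle and
#: discounting units consistent.
MONTH_YEARS = 1.0 / MONTHS_PER_YEAR


@dataclass(frozen=True)
class EventProbability:
    """A probability of an event over a stated time horizon."""

    value: float
    horizon_years: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability must lie in [0, 1], got {self.value}")
        if not self.horizon_years > 0:
            raise ValueError(f"horizon_years must be positive, got {self.horizon_years}")


@dataclass(frozen=True)
class EventRate:
    """A constant event rate in events per year."""

    value: float

    def __post_init__(self) -> None:
        if not (self.value >= 0 and math.isfinite(self.value)):
            raise ValueError(f"rate must be finite and non-negative, got {self.value}")


@dataclass(frozen=True)
class CohortCounts:
    """Event counts observed in a treatment cohort over a follow-up window.

    ``n_at_risk_pd`` is the number of patients ever observed in the
    progressed-disease state; ``n_pd_to_death`` can only count deaths among
    them.
    """

    n_total: int
    n_pfs_to_pd: int
    n_pfs_to_death: int
    n_pd_to_death: int
    n_at_risk_pd: int
    followup_years: float

    def __post_init__(self) -> None:
        counts = (
            self.n_total,
            self.n_pfs_to_pd,
            self.n_pfs_to_death,
            self.n_pd_to_death,
            self.n_at_risk_pd,
        )
        if any(c < 0 for c in counts):
            raise CountInconsistencyError(f"counts must be non-negative: {self}")
        if self.n_total == 0:
            raise InvalidCohortError("cohort has no patients")
        if self.n_pfs_to_pd + self.n_pfs_to_death > self.n_total:
            raise CountInconsistencyError(
                "more PFS exits than patients: "
                f"{self.n_pfs_to_pd} + {self.n_pfs_to_death} > {self.n_total}"
            )
        if not self.n_pd_to_death <= self.n_at_risk_pd <= self.n_pfs_to_pd:
            raise CountInconsistencyError(
                "require n_pd_to_death <= n_at_risk_pd <= n_pfs_to_pd, got "
                f"{self.n_pd_to_death} / {self.n_at_risk_pd} / {self.n_pfs_to_pd}"
            )
        if not self.followup_years > 0:
            raise InvalidCohortError(f"followup_years must be positive, got {self.followup_years}")


@dataclass(frozen=True)
class MonthlyTransitionProbabilities:
    """The three per-month transition probabilities of the disease model."""

    p_pfs_to_pd: float
    p_pfs_to_death: float
    p_pd_to_death: float


def cumulative_event_probability(
    n_event: int, n_total: int, horizon_years: float
) -> EventProbability:
    """Naive cumulative event probability: events over cohort size.

    Parameters
    ----------
    n_event : number of patients with the event during follow-up.
    n_total : cohort size.
    horizon_years : observation span the proportion refers to.
    """
    if n_total <= 0:
        raise InvalidCohortError(f"n_total must be positive, got {n_total}")
    if not 0 <= n_event <= n_total:
        raise CountInconsistencyError(f"need 0 <= n_event <= n_total, got {n_event}/{n_total}")
    return EventProbability(n_event / n_total, horizon_years)


def rate_from_probability(p: EventProbability) -> EventRate:
    """Constant yearly rate implied by a cumulative probability.

    ``r = -ln(1 - P) / t``.  A probability of exactly 1 implies an infinite
    rate and raises :class:`InfiniteRateError` instead of returning ``inf``.
    """
    if p.value >= 1.0:
        raise InfiniteRateError(
            f"cumulative probability {p.value} over {p.horizon_years} y implies an infinite rate"
        )
    return EventRate(-math.log1p(-p.value) / p.horizon_years)


def probability_over_time(r: EventRate, t_years: float) -> EventProbability:
    """Probability of the event within ``t_years`` under constant rate ``r``.

    ``P = 1 - exp(-r t)``; the algebraic inverse of
    :func:`rate_from_probability`.
    """
    if not t_years > 0:
        raise ValueError(f"t_years must be positive, got {t_years}")
    return EventProbability(-math.expm1(-r.value * t_years), t_years)


def monthly_transition_probabilities(counts: CohortCounts) -> MonthlyTransitionProbabilities:
    """Convert cohort counts into monthly transition probabilities.

    Each event's naive cumulative probability over the follow-up window is
    converted to a constant yearly rate and re-expressed over one month.
    The denominator for death after progression is the number of patients
    ever observed in the progressed state.
    """

    def chain(n_event: int, n_at_risk: int) -> float:
        if n_at_risk == 0:
            return 0.0
        p_cum = cumulative_event_probability(n_event, n_at_risk, counts.followup_years)
        return probability_over_time(rate_from_probability(p_cum), MONTH_YEARS).value

    return MonthlyTransitionProbabilities(
        p_pfs_to_pd=chain(counts.n_pfs_to_pd, counts.n_total),
        p_pfs_to_death=chain(counts.n_pfs_to_death, counts.n_total),
        p_pd_to_death=chain(counts.n_pd_to_death, counts.n_at_risk_pd),
    )
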