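"""Synthetic individual-patient data emulating a real-world oncology cohort.

The generator produces censored patient records of the shape a hospital
registry review yields: time to progression, time to death, event flags,
and a monthly stream of state-labelled costs, under administrative
censoring at a fixed follow-up horizon (default 4 years, mirroring a
January 2016 – January 2020 observation window).

Event times are exponential — progression and death-from-PFS compete with
constant yearly rates, and post-progression survival has its own constant
rate — matching the constant-hazard assumption embedded in the
probability/rate conversion chain, so that chain's estimates have a known
estimand.  Monthly costs are Gamma draws per person-month, independent
across months, with a separate (mean, sd) per health state.

The naive cumulative-proportion estimator the conversion chain starts
from ignores censoring and competing risks.  On these synthetic cohorts
that bias can be measured exactly (see :func:`expected_counts`), which is
the module's point: it reproduces a limitation of registry-based
estimation rather than hiding it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conversions import CohortCounts
from .errors import MissingExposureError

__all__ = [
    "CostModel",
    "TrueCohortParameters",
    "IPDRecord",
    "Cohort",
    "generate_cohort",
    "summarize_counts",
    "summarize_costs",
    "expected_counts",
]

MONTHS_PER_YEAR = 12.0


@dataclass(frozen=True)
class CostModel:
    """Gamma-shaped monthly cost for one health state (QAR/month)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("cost mean and sd must be non-negative")


@dataclass(frozen=True)
class TrueCohortParameters:
    """Ground-truth generative parameters for a synthetic cohort.

    Rates are constant yearly hazards; ``followup_years`` is the
    administrative censoring horizon; ``dropout_rate`` (yearly) adds
    optional exponential loss to follow-up (0 = none, the default).
    """

    n_patients: int
    r_pfs_to_pd: float
    r_pfs_to_death: float
    r_pd_to_death: float
    cost_pfs: CostModel = field(default=CostModel(11_628.5, 6_839.0))
    cost_pd: CostModel = field(default=CostModel(2_942.6, 2_224.3))
    followup_years: float = 4.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if min(self.r_pfs_to_pd, self.r_pfs_to_death, self.r_pd_to_death) < 0:
            raise ValueError("rates must be non-negative")
        if not self.followup_years > 0:
            raise ValueError("followup_years must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be non-negative")


@dataclass(frozen=True)
class IPDRecord:
    """One synthetic patient, times in months from treatment start."""

    patient_id: int
    time_to_progression: float  # progression or censoring time
    progressed: bool
    time_to_death: float  # death or censoring time
    died: bool


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: per-patient events plus a monthly cost stream.

    ``patients`` has one row per patient (id, t_prog, prog_event, t_death,
    death_event; times in months); ``costs`` is long-format with one row
    per observed person-month (id, month, state, cost).
    """

    patients: pd.DataFrame
    costs: pd.DataFrame
    params: TrueCohortParameters

    def __len__(self) -> int:
        return len(self.patients)

    def records(self) -> list[IPDRecord]:
        return [
            IPDRecord(
                patient_id=int(r.id),
                time_to_progression=float(r.t_prog),
                progressed=bool(r.prog_event),
                time_to_death=float(r.t_death),
                died=bool(r.death_event),
            )
            for r in self.patients.itertuples(index=False)
        ]


def _exponential(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def generate_cohort(p: TrueCohortParameters) -> Cohort:
    """Simulate a censored cohort under the constant-hazard model.

    Time to PFS exit is exponential with rate ``r_pfs_to_pd +
    r_pfs_to_death``; the exit cause is progression with probability
    proportional to its rate.  Post-progression survival is exponential
    with ``r_pd_to_death``.  Everything is administratively censored at
    ``followup_years`` (and, optionally, at an exponential dropout time).
    Deterministic for a given ``p.seed``.
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_patients
    exit_rate = p.r_pfs_to_pd + p.r_pfs_to_death
    t_exit = _exponential(rng, exit_rate, n)  # years
    is_prog = rng.random(n) < (p.r_pfs_to_pd / exit_rate if exit_rate > 0 else 0.0)
    t_pps = _exponential(rng, p.r_pd_to_death, n)  # post-progression survival

    censor = np.full(n, p.followup_years)
    if p.dropout_rate > 0:
        censor = np.minimum(censor, _exponential(rng, p.dropout_rate, n))

    t_prog_true = np.where(is_prog, t_exit, np.inf)
    t_death_true = np.where(is_prog, t_exit + t_pps, t_exit)

    prog_event = t_prog_true <= censor
    death_event = t_death_true <= censor
    # progression observation ends at death or censoring, whichever first
    t_prog = np.minimum(t_prog_true, np.minimum(t_death_true, censor)) * MONTHS_PER_YEAR
    t_death = np.minimum(t_death_true, censor) * MONTHS_PER_YEAR

    patients = pd.DataFrame(
        {
            "id": np.arange(n),
            "t_prog": t_prog,
            "prog_event": prog_event,
            "t_death": t_death,
            "death_event": death_event,
        }
    )

    # Monthly cost stream: month m covers (m-1, m]; a month is billed to
    # the state occupied at its start, and only while alive and on study.
    t_prog_m = np.where(prog_event, t_prog, np.inf)
    end_m = np.minimum(t_death, censor * MONTHS_PER_YEAR)
    n_months = np.ceil(end_m - 1e-12).astype(int).clip(min=0)
    total = int(n_months.sum())
    ids = np.repeat(np.arange(n), n_months)
    offsets = np.concatenate(([0], np.cumsum(n_months)[:-1]))
    months = np.arange(total) - np.repeat(offsets, n_months) + 1
    states = np.where((months - 1) >= t_prog_m[ids], "pd", "pfs")
    cost = np.empty(total)
    for state, cm in (("pfs", p.cost_pfs), ("pd", p.cost_pd)):
        mask = states == state
        k = int(mask.sum())
        if k == 0:
            continue
        if cm.sd == 0 or cm.mean == 0:
            cost[mask] = cm.mean
        else:
            shape = (cm.mean / cm.sd) ** 2
            cost[mask] = rng.gamma(shape, cm.sd**2 / cm.mean, size=k)
    costs = pd.DataFrame({"id": ids, "month": months, "state": states, "cost": cost})
    return Cohort(patients=patients, costs=costs, params=p)


def summarize_counts(cohort: Cohort) -> CohortCounts:
    """Reduce a cohort to the event counts the conversion chain consumes."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    pt = cohort.patients
    progressed = pt["prog_event"]
    died = pt["death_event"]
    return CohortCounts(
        n_total=len(pt),
        n_pfs_to_pd=int(progressed.sum()),
        n_pfs_to_death=int((died & ~progressed).sum()),
        n_pd_to_death=int((died & progressed).sum()),
        n_at_risk_pd=int(progressed.sum()),
        followup_years=cohort.params.followup_years,
    )


def summarize_costs(cohort: Cohort) -> dict[str, float]:
    """Mean monthly cost per state, pooled over observed person-months.

    A state with no observed person-months has no defined mean and raises
    :class:`MissingExposureError` rather than reporting 0.
    """
    out: dict[str, float] = {}
    for state in ("pfs", "pd"):
        sub = cohort.costs.loc[cohort.costs["state"] == state, "cost"]
        if sub.empty:
            raise MissingExposureError(f"no person-months observed in state {state!r}")
        out[state] = float(sub.mean())
    return out


def expected_counts(p: TrueCohortParameters) -> CohortCounts:
    """Exact expected event counts under the generative model (rounded).

    These are the estimands of :func:`summarize_counts` — the naive
    estimator's *targets*, which differ from the planted rates whenever
    censoring or competing risks bite.  Used to separate Monte-Carlo noise
    from structural bias in recovery experiments.
    """
    T = p.followup_years
    R = p.r_pfs_to_pd + p.r_pfs_to_death
    n = p.n_patients
    if R > 0:
        p_exit = -math.expm1(-R * T)
        p_prog = p.r_pfs_to_pd / R * p_exit
        p_pfs_death = p.r_pfs_to_death / R * p_exit
    else:
        p_prog = p_pfs_death = 0.0
    # P(progress at u, then die before T): integrate the exponential
    # post-progression survival over the progression-time density.
    r23 = p.r_pd_to_death
    if p.r_pfs_to_pd > 0 and r23 > 0:
        if abs(R - r23) > 1e-12:
            p_pd_death = (
                p.r_pfs_to_pd
                / R
                * (-math.expm1(-R * T) - R / (R - r23) * (math.exp(-r23 * T) - math.exp(-R * T)))
            )
        else:
            p_pd_death = p.r_pfs_to_pd / R * (-math.expm1(-R * T) - R * T * math.exp(-R * T))
    else:
        p_pd_death = 0.0
    return CohortCounts(
        n_total=n,
        n_pfs_to_pd=round(n * p_prog),
        n_pfs_to_death=round(n * p_pfs_death),
        n_pd_to_death=round(n * p_pd_death),
        n_at_risk_pd=round(n * p_prog),
        followup_years=T,
    )
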