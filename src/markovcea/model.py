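"""Three-state Markov cohort engine for advanced breast cancer treatment.

The model has three health states — progression-free (PFS), progressed
disease (PD) and death — with unidirectional transitions only: a patient
may stay put, progress, or die, and death is absorbing.  The whole cohort
enters in PFS.  Cycles are monthly; the default horizon is 120 cycles
(10 years).  Costs accrue per month of state occupancy, life-years and
QALYs per year of (utility-weighted) occupancy, and everything is
discounted at an annual rate.

Within-cycle correction credits each cycle with the trapezoidal average of
its start and end occupancy, the standard life-table correction for the
discretisation bias of crediting whole cycles at either endpoint.  The
matching discount convention is mid-cycle: cycle ``k`` (1-based) is
discounted by ``(1 + rate) ** (-(k - 0.5) * cycle_length_years)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidStrategyError

__all__ = [
    "STATES",
    "Correction",
    "DiscountTiming",
    "StrategyInputs",
    "ModelConfig",
    "MarkovTrace",
    "StrategyResult",
    "build_transition_matrix",
    "run_cohort_trace",
    "accumulate_outcomes",
    "run_strategy",
    "batch_outcomes",
]

STATES = ("pfs", "pd", "death")
_PROB_TOL = 1e-12


class Correction(str, enum.Enum):
    """How state occupancy is credited within a cycle."""

    NONE = "none"  # end-of-cycle membership
    WITHIN_CYCLE = "within_cycle"  # trapezoidal (half-cycle) credit
    START = "start"  # start-of-cycle membership


class DiscountTiming(str, enum.Enum):
    CYCLE_START = "cycle_start"
    CYCLE_MID = "cycle_mid"
    CYCLE_END = "cycle_end"


@dataclass(frozen=True)
class StrategyInputs:
    """One treatment arm: monthly state costs, utilities and transition
    probabilities.

    Costs are QAR per patient-month of state occupancy; utilities are
    dimensionless weights in [0, 1]; probabilities are per one-month cycle.
    """

    name: str
    cost_pfs_month: float
    cost_pd_month: float
    utility_pfs: float
    utility_pd: float
    p_pfs_to_pd: float
    p_pfs_to_death: float
    p_pd_to_death: float

    def __post_init__(self) -> None:
        for fname in ("p_pfs_to_pd", "p_pfs_to_death", "p_pd_to_death"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise InvalidStrategyError(f"{self.name}: {fname}={v} outside [0, 1]")
        if self.p_pfs_to_pd + self.p_pfs_to_death > 1.0 + _PROB_TOL:
            raise InvalidStrategyError(
                f"{self.name}: PFS exit probabilities sum to "
                f"{self.p_pfs_to_pd + self.p_pfs_to_death} > 1"
            )
        for fname in ("cost_pfs_month", "cost_pd_month"):
            if getattr(self, fname) < 0:
                raise InvalidStrategyError(f"{self.name}: {fname} must be >= 0")
        for fname in ("utility_pfs", "utility_pd"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise InvalidStrategyError(f"{self.name}: {fname}={v} outside [0, 1]")

    def with_(self, **changes) -> "StrategyInputs":
        """Copy with selected fields replaced (re-validates)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelConfig:
    """Global model conventions shared by both arms."""

    horizon_cycles: int = 120
    cycle_length_years: float = 1.0 / 12.0
    annual_discount_rate: float = 0.035
    correction: Correction = Correction.WITHIN_CYCLE
    discount_timing: DiscountTiming = DiscountTiming.CYCLE_MID
    discount_life_years: bool = True
    wtp_very_cost_effective: float = 192_050.0  # 1x Qatari GDP/capita, QAR/QALY
    wtp_cost_effective: float = 576_150.0  # 3x GDP/capita, QAR/QALY

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValueError("annual_discount_rate must lie in [0, 1)")
        if not self.cycle_length_years > 0:
            raise ValueError("cycle_length_years must be positive")
        if self.wtp_cost_effective <= 0 or self.wtp_very_cost_effective <= 0:
            raise ValueError("WTP thresholds must be positive")

    def discount_factors(self) -> np.ndarray:
        """Per-cycle discount factors for cycles 1..horizon."""
        k = np.arange(1, self.horizon_cycles + 1, dtype=float)
        offset = {
            DiscountTiming.CYCLE_START: 1.0,
            DiscountTiming.CYCLE_MID: 0.5,
            DiscountTiming.CYCLE_END: 0.0,
        }[self.discount_timing]
        return (1.0 + self.annual_discount_rate) ** (-(k - offset) * self.cycle_length_years)


def build_transition_matrix(s: StrategyInputs) -> np.ndarray:
    """Row-stochastic 3x3 matrix over (PFS, PD, death).

    PD cannot return to PFS and death is absorbing, so the matrix is upper
    triangular with a unit last row.
    """
    m = np.array(
        [
            [1.0 - s.p_pfs_to_pd - s.p_pfs_to_death, s.p_pfs_to_pd, s.p_pfs_to_death],
            [0.0, 1.0 - s.p_pd_to_death, s.p_pd_to_death],
            [0.0, 0.0, 1.0],
        ]
    )
    if (m < -_PROB_TOL).any():
        raise InvalidStrategyError(f"{s.name}: transition probabilities sum above 1")
    return np.clip(m, 0.0, 1.0)


@dataclass(frozen=True)
class MarkovTrace:
    """Cohort trace: occupancy at cycle boundaries plus per-cycle credit.

    ``occupancy[k]`` is the state distribution after ``k`` cycles
    (``occupancy[0] = (1, 0, 0)`` is model entry); ``credited[k-1]`` is the
    occupancy credited to cycle ``k`` under the configured correction and
    ``discount[k-1]`` its discount factor.
    """

    occupancy: np.ndarray  # (horizon+1, 3)
    credited: np.ndarray  # (horizon, 3)
    discount: np.ndarray  # (horizon,)
    config: ModelConfig = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Cycle-indexed trace table (cycles 1..horizon)."""
        h = self.credited.shape[0]
        return pd.DataFrame(
            {
                "cycle": np.arange(1, h + 1),
                "pfs": self.occupancy[1:, 0],
                "pd": self.occupancy[1:, 1],
                "death": self.occupancy[1:, 2],
                "credited_pfs": self.credited[:, 0],
                "credited_pd": self.credited[:, 1],
                "discount_factor": self.discount,
            }
        )


def run_cohort_trace(m: np.ndarray, cfg: ModelConfig) -> MarkovTrace:
    """Propagate the whole cohort from PFS through ``cfg.horizon_cycles``."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise InvalidStrategyError("transition matrix must be 3x3 row-stochastic")
    h = cfg.horizon_cycles
    occ = np.empty((h + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for k in range(1, h + 1):
        occ[k] = occ[k - 1] @ m
    if cfg.correction is Correction.WITHIN_CYCLE:
        credited = 0.5 * (occ[:-1] + occ[1:])
    elif cfg.correction is Correction.START:
        credited = occ[:-1].copy()
    else:
        credited = occ[1:].copy()
    return MarkovTrace(occ, credited, cfg.discount_factors(), cfg)


@dataclass(frozen=True)
class StrategyResult:
    """Discounted lifetime totals for one arm over the model horizon."""

    name: str
    total_cost: float
    cost_pfs: float
    cost_pd: float
    life_years: float
    life_years_undiscounted: float
    qalys: float
    config: ModelConfig = field(repr=False)

    @property
    def life_months(self) -> float:
        return self.life_years * 12.0

    @property
    def qaly_months(self) -> float:
        return self.qalys * 12.0


def accumulate_outcomes(trace: MarkovTrace, s: StrategyInputs, cfg: ModelConfig) -> StrategyResult:
    """Sum discounted costs, life-years and QALYs over the trace.

    Death accrues neither cost nor utility; there are no one-off transition
    costs.  Each cycle contributes ``cycle_length_years`` of (possibly
    utility-weighted) survival for its credited alive occupancy.
    """
    if trace.config != cfg:
        raise ValueError("trace was produced under a different ModelConfig")
    pfs, pd_ = trace.credited[:, 0], trace.credited[:, 1]
    v = trace.discount
    cl = cfg.cycle_length_years
    cost_pfs = float((pfs * v).sum()) * s.cost_pfs_month
    cost_pd = float((pd_ * v).sum()) * s.cost_pd_month
    ly_weights = v if cfg.discount_life_years else np.ones_like(v)
    life_years = float(((pfs + pd_) * ly_weights).sum()) * cl
    life_years_undisc = float((pfs + pd_).sum()) * cl
    qalys = float(((pfs * s.utility_pfs + pd_ * s.utility_pd) * v).sum()) * cl
    return StrategyResult(
        name=s.name,
        total_cost=cost_pfs + cost_pd,
        cost_pfs=cost_pfs,
        cost_pd=cost_pd,
        life_years=life_years,
        life_years_undiscounted=life_years_undisc,
        qalys=qalys,
        config=cfg,
    )


def run_strategy(s: StrategyInputs, cfg: ModelConfig) -> StrategyResult:
    """Build the matrix, run the trace and accumulate outcomes for one arm."""
    return accumulate_outcomes(run_cohort_trace(build_transition_matrix(s), cfg), s, cfg)


def batch_outcomes(
    p_pfs_to_pd: np.ndarray,
    p_pfs_to_death: np.ndarray,
    p_pd_to_death: np.ndarray,
    cost_pfs_month: np.ndarray,
    cost_pd_month: np.ndarray,
    utility_pfs: np.ndarray,
    utility_pd: np.ndarray,
    cfg: ModelConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised engine: run many parameter sets through the same trace.

    All arguments broadcast to a common draw dimension ``n``.  The cycle
    recursion, credit rule and discounting are identical to the scalar path
    (:func:`run_strategy`); this exists so that Monte-Carlo re-evaluation of
    thousands of parameter draws stays cheap.

    Returns ``(total_cost, life_years, qalys)`` arrays of shape ``(n,)``.
    """
    p12, p13, p23, cpfs, cpd, upfs, upd = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float)) for a in (
            p_pfs_to_pd, p_pfs_to_death, p_pd_to_death,
            cost_pfs_month, cost_pd_month, utility_pfs, utility_pd,
        ))
    )
    if (p12 + p13 > 1.0 + _PROB_TOL).any() or (p23 > 1.0).any() or (p12 < 0).any() or (
        p13 < 0
    ).any() or (p23 < 0).any():
        raise InvalidStrategyError("a draw violates the transition-probability invariants")
    n = p12.shape[0]
    stay_pfs = 1.0 - p12 - p13
    stay_pd = 1.0 - p23
    v = cfg.discount_factors()
    ly_w = v if cfg.discount_life_years else np.ones_like(v)
    s_pfs = np.ones(n)
    s_pd = np.zeros(n)
    cost = np.zeros(n)
    ly = np.zeros(n)
    qaly = np.zeros(n)
    for k in range(cfg.horizon_cycles):
        n_pfs = s_pfs * stay_pfs
        n_pd = s_pfs * p12 + s_pd * stay_pd
        if cfg.correction is Correction.WITHIN_CYCLE:
            c_pfs, c_pd = 0.5 * (s_pfs + n_pfs), 0.5 * (s_pd + n_pd)
        elif cfg.correction is Correction.START:
            c_pfs, c_pd = s_pfs, s_pd
        else:
            c_pfs, c_pd = n_pfs, n_pd
        cost += (c_pfs * cpfs + c_pd * cpd) * v[k]
        ly += (c_pfs + c_pd) * ly_w[k]
        qaly += (c_pfs * upfs + c_pd * upd) * v[k]
        s_pfs, s_pd = n_pfs, n_pd
    cl = cfg.cycle_length_years
    return cost, ly * cl, qaly * cl
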