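"""Incremental cost-effectiveness metrics, dominance and WTP decisions.

Conventions: the intervention is compared against the comparator, so all
deltas are intervention minus comparator.  A strategy *dominates* when it
is no more costly and no less effective (and not identical); ratios (ICER
per life-year, ICUR per QALY) are reported only in the trade-off quadrants
where they are meaningful.  Net monetary benefit at willingness-to-pay
``wtp`` is ``wtp * dQALY - dCost``; adoption requires strictly positive
NMB.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .model import ModelConfig, StrategyInputs, StrategyResult, run_strategy

__all__ = [
    "Dominance",
    "CEAResult",
    "TwoArmModel",
    "TwoArmResult",
    "classify_dominance",
    "incremental_analysis",
    "decision_at_wtp",
]


class Dominance(str, enum.Enum):
    """Position of the incremental (effect, cost) point on the CE plane."""

    INTERVENTION_DOMINANT = "intervention_dominant"  # cheaper-or-equal, at-least-as-effective
    INTERVENTION_DOMINATED = "intervention_dominated"  # dearer, less effective
    TRADE_OFF_NE = "trade_off_ne"  # dearer but more effective
    TRADE_OFF_SW = "trade_off_sw"  # cheaper but less effective
    INDIFFERENT = "indifferent"  # identical cost and effect


def classify_dominance(delta_cost: float, delta_effect: float) -> Dominance:
    """Classify an incremental point; total and mutually exclusive.

    Axis points are folded into the adjacent weak-dominance category: e.g.
    equal cost with an effect gain counts as dominant.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise ValueError("deltas must be finite")
    if delta_cost == 0.0 and delta_effect == 0.0:
        return Dominance.INDIFFERENT
    if delta_cost <= 0.0 and delta_effect >= 0.0:
        return Dominance.INTERVENTION_DOMINANT
    if delta_cost >= 0.0 and delta_effect <= 0.0:
        return Dominance.INTERVENTION_DOMINATED
    if delta_cost > 0.0:
        return Dominance.TRADE_OFF_NE
    return Dominance.TRADE_OFF_SW


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of two strategies run under one config."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    dominance: Dominance
    dominance_ly: Dominance

    @property
    def icer(self) -> float | None:
        """Incremental cost per life-year; ``None`` off the trade-off quadrants."""
        if self.dominance_ly in (Dominance.TRADE_OFF_NE, Dominance.TRADE_OFF_SW):
            return self.delta_cost / self.delta_ly
        return None

    @property
    def icur(self) -> float | None:
        """Incremental cost per QALY; ``None`` off the trade-off quadrants."""
        if self.dominance in (Dominance.TRADE_OFF_NE, Dominance.TRADE_OFF_SW):
            return self.delta_cost / self.delta_qaly
        return None

    def nmb(self, wtp: float) -> float:
        """Net monetary benefit of the intervention at ``wtp`` QAR/QALY."""
        return wtp * self.delta_qaly - self.delta_cost

    def verdict(self) -> str:
        """Human-readable summary mirroring published result tables."""
        if self.dominance is Dominance.INTERVENTION_DOMINANT:
            return f"{self.intervention} dominates {self.comparator}"
        if self.dominance is Dominance.INTERVENTION_DOMINATED:
            return f"{self.intervention} is dominated by {self.comparator}"
        if self.dominance is Dominance.INDIFFERENT:
            return "strategies are indifferent"
        return f"ICUR = {self.icur:,.1f} QAR/QALY"


def incremental_analysis(intervention: StrategyResult, comparator: StrategyResult) -> CEAResult:
    """Incremental cost, life-year and QALY comparison of two arms.

    Both results must come from the same :class:`ModelConfig`; comparing
    runs under different horizons or discounting conventions is a modelling
    error, not a numerical one.
    """
    if intervention.config != comparator.config:
        raise ValueError("strategies were run under different model configurations")
    dc = intervention.total_cost - comparator.total_cost
    dly = intervention.life_years - comparator.life_years
    dq = intervention.qalys - comparator.qalys
    return CEAResult(
        intervention=intervention.name,
        comparator=comparator.name,
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dq,
        dominance=classify_dominance(dc, dq),
        dominance_ly=classify_dominance(dc, dly),
    )


@dataclass(frozen=True)
class TwoArmResult:
    """Both arms' lifetime totals plus their incremental comparison."""

    intervention: StrategyResult
    comparator: StrategyResult
    cea: CEAResult


@dataclass(frozen=True)
class TwoArmModel:
    """A fully specified two-strategy comparison ready to run.

    The intervention/comparator orientation is fixed at construction (for
    the shipped base case: ribociclib vs palbociclib) so every downstream
    delta has an unambiguous sign.
    """

    intervention: "StrategyInputs"
    comparator: "StrategyInputs"
    config: "ModelConfig"

    def run(self) -> TwoArmResult:
        res_i = run_strategy(self.intervention, self.config)
        res_c = run_strategy(self.comparator, self.config)
        return TwoArmResult(res_i, res_c, incremental_analysis(res_i, res_c))


def decision_at_wtp(r: CEAResult, wtp: float) -> tuple[str, float]:
    """Adopt/reject decision and NMB at a willingness-to-pay threshold.

    Adoption requires strictly positive net monetary benefit, so an ICUR
    exactly at the threshold (NMB = 0) is rejected; a dominant intervention
    always has positive NMB at any positive WTP unless it is indifferent.
    """
    if not wtp > 0:
        raise ValueError("wtp must be positive")
    nmb = r.nmb(wtp)
    return ("adopt" if nmb > 0 else "reject"), nmb
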