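"""One-way deterministic sensitivity analysis, tornado ranking, and
threshold (break-even) search.

Each parameter is moved to its lower and upper bound in turn while every
other input stays at base case, the full two-arm model is re-run, and the
incremental comparison re-evaluated.  Parameters are ranked for the
tornado diagram by the spread of incremental net monetary benefit across
their two bounds — NMB rather than the ICUR, because the ratio is
undefined in the dominance regions that occur throughout this comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import pandas as pd

from .cea import TwoArmModel, TwoArmResult
from .errors import AmbiguousThresholdError

__all__ = ["ParameterSpec", "DSARow", "apply_parameter", "one_way", "run_dsa", "tornado", "threshold_search"]

#: Which arm(s) of the model a parameter belongs to.  "both" is used for
#: inputs shared between arms (PD cost, PD utility); "config" addresses a
#: ModelConfig field such as the discount rate.
ARMS = ("intervention", "comparator", "both", "config")


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain input with its deterministic bounds."""

    id: str
    arm: str  # one of ARMS
    field: str  # StrategyInputs (or ModelConfig) field name
    base_value: float
    lower_bound: float
    upper_bound: float
    bound_source: str = ""

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"{self.id}: arm must be one of {ARMS}, got {self.arm!r}")
        if not self.lower_bound <= self.base_value <= self.upper_bound:
            raise ValueError(
                f"{self.id}: need lower <= base <= upper, got "
                f"{self.lower_bound} / {self.base_value} / {self.upper_bound}"
            )


def apply_parameter(model: TwoArmModel, spec: ParameterSpec, value: float) -> TwoArmModel:
    """Return a copy of the model with one parameter set to ``value``.

    Validation of the perturbed inputs (probability sums, utility range)
    happens in the strategy/config constructors, so an out-of-range bound
    surfaces as the usual invariant error.
    """
    if spec.arm == "config":
        cfg = replace(model.config, **{spec.field: value})
        return TwoArmModel(model.intervention, model.comparator, cfg)
    interv, comp = model.intervention, model.comparator
    if spec.arm in ("intervention", "both"):
        interv = interv.with_(**{spec.field: value})
    if spec.arm in ("comparator", "both"):
        comp = comp.with_(**{spec.field: value})
    return TwoArmModel(interv, comp, model.config)


@dataclass(frozen=True)
class DSARow:
    """Outcome of one model re-run with a single parameter perturbed."""

    parameter_id: str
    bound: str  # "lower" | "upper" | "base"
    value: float
    result: TwoArmResult

    @property
    def conclusion(self) -> str:
        return self.result.cea.verdict()

    def as_dict(self) -> dict:
        cea = self.result.cea
        return {
            "parameter": self.parameter_id,
            "bound": self.bound,
            "value": self.value,
            "cost_intervention": self.result.intervention.total_cost,
            "qalys_intervention": self.result.intervention.qalys,
            "cost_comparator": self.result.comparator.total_cost,
            "qalys_comparator": self.result.comparator.qalys,
            "delta_cost": cea.delta_cost,
            "delta_qaly": cea.delta_qaly,
            "icur": cea.icur,
            "conclusion": self.conclusion,
        }


def one_way(spec: ParameterSpec, model: TwoArmModel) -> tuple[DSARow, DSARow]:
    """Re-run the model at the parameter's lower and upper bound."""
    rows = []
    for bound, value in (("lower", spec.lower_bound), ("upper", spec.upper_bound)):
        rows.append(DSARow(spec.id, bound, value, apply_parameter(model, spec, value).run()))
    return tuple(rows)


def run_dsa(specs: Iterable[ParameterSpec], model: TwoArmModel) -> list[tuple[DSARow, DSARow]]:
    return [one_way(spec, model) for spec in specs]


def tornado(
    rows: Sequence[tuple[DSARow, DSARow]], wtp: float
) -> pd.DataFrame:
    """Rank parameters by the spread of incremental NMB across their bounds.

    Returns one row per parameter, descending by spread, carrying both
    bound outcomes so a tornado diagram can be drawn directly.
    """
    records = []
    for lo, hi in rows:
        nmb_lo = lo.result.cea.nmb(wtp)
        nmb_hi = hi.result.cea.nmb(wtp)
        records.append(
            {
                "parameter": lo.parameter_id,
                "value_lower": lo.value,
                "value_upper": hi.value,
                "nmb_lower": nmb_lo,
                "nmb_upper": nmb_hi,
                "spread": abs(nmb_hi - nmb_lo),
                "conclusion_lower": lo.conclusion,
                "conclusion_upper": hi.conclusion,
            }
        )
    out = pd.DataFrame.from_records(records)
    return out.sort_values("spread", ascending=False, kind="stable").reset_index(drop=True)


def threshold_search(
    spec: ParameterSpec,
    predicate: Callable[[TwoArmResult], bool],
    model: TwoArmModel,
    interval: tuple[float, float] | None = None,
    tol: float | None = None,
    scan_points: int = 64,
) -> float | None:
    """Bisection search for the parameter value where a decision flips.

    The predicate (e.g. "the intervention strictly dominates") is first
    evaluated on a ``scan_points`` grid over ``interval`` (default: the
    spec's bounds).  A constant predicate returns ``None``; more than one
    flip on the grid raises :class:`AmbiguousThresholdError` because a
    bisection answer would then depend on the bracket.  Tolerance defaults
    to 1e-4 of the base value (or of the interval width when the base is 0).
    """
    lo, hi = interval if interval is not None else (spec.lower_bound, spec.upper_bound)
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    if tol is None:
        scale = abs(spec.base_value) if spec.base_value != 0 else (hi - lo)
        tol = 1e-4 * scale

    def decide(x: float) -> bool:
        return bool(predicate(apply_parameter(model, spec, x).run()))

    grid = [lo + (hi - lo) * i / (scan_points - 1) for i in range(scan_points)]
    values = [decide(x) for x in grid]
    flips = [i for i in range(1, scan_points) if values[i] != values[i - 1]]
    if not flips:
        return None
    if len(flips) > 1:
        raise AmbiguousThresholdError(
            f"{spec.id}: predicate changes sign {len(flips)} times on the scan grid"
        )
    a, b = grid[flips[0] - 1], grid[flips[0]]
    fa = values[flips[0] - 1]
    while b - a > tol:
        mid = 0.5 * (a + b)
        if decide(mid) == fa:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)
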