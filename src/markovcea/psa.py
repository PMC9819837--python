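"""Probabilistic sensitivity analysis by Monte-Carlo simulation.

Uncertain inputs are given Gamma (costs) or Beta (probabilities,
utilities) distributions parameterised by method of moments from a
published mean and standard deviation.  Each draw samples all parameters
independently, rebuilds both treatment arms, re-runs the full Markov
engine, and records each arm's discounted lifetime cost and QALYs.  The
cloud of incremental (QALY, cost) points is then classified on the
incremental cost-effectiveness (ICE) plane and summarised as a
cost-effectiveness acceptability curve (CEAC).

Two "favoring the intervention" aggregates are reported because the
literature is not consistent about the NE quadrant: ``favoring_quadrant``
counts every more-effective draw that is dominant or dearer-but-more-
effective (the whole NE quadrant), while ``favoring_below_wtp`` restricts
the NE quadrant to draws whose ICUR falls below the willingness-to-pay
threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cea import TwoArmModel
from .errors import InfeasibleBetaError
from .model import batch_outcomes

__all__ = [
    "DistributionFamily",
    "ParameterDistribution",
    "PSAResult",
    "IceSummary",
    "fit_gamma_moments",
    "fit_beta_moments",
    "run_psa",
    "classify_ice",
    "ceac",
]

class DistributionFamily(str, enum.Enum):
    GAMMA = "gamma"
    BETA = "beta"


def fit_gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) with exactly the requested mean and SD."""
    if not (mean > 0 and sd > 0):
        raise ValueError(f"gamma fit needs mean > 0 and sd > 0, got {mean}, {sd}")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) with exactly the requested mean and SD.

    Feasibility requires ``sd**2 < mean * (1 - mean)``; the Beta family
    cannot represent a larger variance at that mean.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta fit needs mean in (0, 1), got {mean}")
    if not sd > 0:
        raise ValueError(f"beta fit needs sd > 0, got {sd}")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleBetaError(
            f"variance {var:.4g} >= mean(1-mean) = {mean * (1 - mean):.4g}; no Beta exists"
        )
    k = mean * (1.0 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


@dataclass(frozen=True)
class ParameterDistribution:
    """Distributional assumption for one uncertain input."""

    id: str
    arm: str  # "intervention" | "comparator" | "both"
    field: str  # StrategyInputs field name
    family: DistributionFamily
    mean: float
    sd: float

    def __post_init__(self) -> None:
        # fitting validates feasibility eagerly
        self.moment_parameters()

    def moment_parameters(self) -> tuple[float, float]:
        if self.family is DistributionFamily.GAMMA:
            return fit_gamma_moments(self.mean, self.sd)
        return fit_beta_moments(self.mean, self.sd)

    def frozen(self) -> stats.rv_continuous:
        """The scipy frozen distribution implied by the moments."""
        a, b = self.moment_parameters()
        if self.family is DistributionFamily.GAMMA:
            return stats.gamma(a, scale=b)
        return stats.beta(a, b)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a, b = self.moment_parameters()
        if self.family is DistributionFamily.GAMMA:
            return rng.gamma(a, b, size=n)
        return rng.beta(a, b, size=n)


@dataclass(frozen=True)
class PSAResult:
    """Per-draw outcomes of a Monte-Carlo PSA for both arms."""

    draws: pd.DataFrame  # columns: draw, cost/qaly per arm, deltas
    parameter_samples: pd.DataFrame  # one column per sampled parameter
    seed: int
    n_redraws: int  # draws rejected for violating the PFS row sum
    intervention: str = "intervention"
    comparator: str = "comparator"

    @property
    def n(self) -> int:
        return len(self.draws)

    def summary(self) -> pd.DataFrame:
        cols = [c for c in self.draws.columns if c != "draw"]
        return self.draws[cols].agg(["mean", "std"])


def _assign_samples(dist: ParameterDistribution, samples: np.ndarray, base: dict) -> None:
    if dist.arm in ("intervention", "both"):
        base[("intervention", dist.field)] = samples
    if dist.arm in ("comparator", "both"):
        base[("comparator", dist.field)] = samples


def run_psa(
    model: TwoArmModel,
    distributions: list[ParameterDistribution],
    n: int = 10_000,
    seed: int = 20201,
    max_redraw_rounds: int = 100,
) -> PSAResult:
    """Monte-Carlo re-evaluation of the two-arm model.

    All parameters are sampled independently, parameter-major, from a
    ``numpy.random.default_rng(seed)`` stream.  Probability draws are
    combined with the arm's fixed complementary probabilities; if a draw
    makes a PFS row sum exceed 1 it is rejected and redrawn (the count is
    recorded on the result).  Identical seeds give identical results.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = [d.id for d in distributions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate distribution ids")
    rng = np.random.default_rng(seed)

    samples: dict[str, np.ndarray] = {d.id: d.sample(rng, n) for d in distributions}

    # Start each arm's parameter vectors at base case, then overwrite the
    # sampled fields.
    arms = {"intervention": model.intervention, "comparator": model.comparator}
    fields = (
        "p_pfs_to_pd", "p_pfs_to_death", "p_pd_to_death",
        "cost_pfs_month", "cost_pd_month", "utility_pfs", "utility_pd",
    )
    values = {
        (arm, f): np.full(n, getattr(s, f)) for arm, s in arms.items() for f in fields
    }
    for d in distributions:
        _assign_samples(d, samples[d.id].copy(), values)

    # Reject-and-redraw any draw whose sampled PFS exit probabilities sum
    # above 1 for either arm (possible only in the far Beta tail).
    n_redraws = 0
    prob_dists = [
        d for d in distributions if d.field in ("p_pfs_to_pd", "p_pfs_to_death")
    ]
    for _ in range(max_redraw_rounds):
        bad = np.zeros(n, dtype=bool)
        for arm in arms:
            bad |= values[(arm, "p_pfs_to_pd")] + values[(arm, "p_pfs_to_death")] > 1.0
        if not bad.any():
            break
        n_redraws += int(bad.sum())
        for d in prob_dists:
            fresh = d.sample(rng, int(bad.sum()))
            for arm_key in ("intervention", "comparator"):
                if d.arm in (arm_key, "both"):
                    values[(arm_key, d.field)][bad] = fresh
            samples[d.id][bad] = fresh
    else:
        raise RuntimeError("could not produce valid probability draws")

    out = {"draw": np.arange(n)}
    for arm in ("intervention", "comparator"):
        cost, ly, qaly = batch_outcomes(
            values[(arm, "p_pfs_to_pd")],
            values[(arm, "p_pfs_to_death")],
            values[(arm, "p_pd_to_death")],
            values[(arm, "cost_pfs_month")],
            values[(arm, "cost_pd_month")],
            values[(arm, "utility_pfs")],
            values[(arm, "utility_pd")],
            model.config,
        )
        out[f"cost_{arm}"] = cost
        out[f"ly_{arm}"] = ly
        out[f"qaly_{arm}"] = qaly
    out["delta_cost"] = out["cost_intervention"] - out["cost_comparator"]
    out["delta_qaly"] = out["qaly_intervention"] - out["qaly_comparator"]
    return PSAResult(
        draws=pd.DataFrame(out),
        parameter_samples=pd.DataFrame(samples),
        seed=seed,
        n_redraws=n_redraws,
        intervention=model.intervention.name,
        comparator=model.comparator.name,
    )


@dataclass(frozen=True)
class IceSummary:
    """Quadrant shares of the incremental cost-effectiveness plane.

    ``dominant`` + ``ne_below_wtp`` + ``ne_above_wtp`` + ``sw`` +
    ``dominated`` = 1 exactly; axis draws are folded into the weak
    dominance categories as in :func:`markovcea.cea.classify_dominance`.
    """

    wtp: float
    dominant: float
    ne_below_wtp: float
    ne_above_wtp: float
    sw: float
    dominated: float
    n: int = field(default=0)

    @property
    def favoring_below_wtp(self) -> float:
        """Dominant draws plus NE-quadrant draws with ICUR below WTP."""
        return self.dominant + self.ne_below_wtp

    @property
    def favoring_quadrant(self) -> float:
        """Dominant draws plus the entire more-costly/more-effective quadrant."""
        return self.dominant + self.ne_below_wtp + self.ne_above_wtp


def classify_ice(result: PSAResult, wtp: float) -> IceSummary:
    """Classify every PSA draw into an ICE-plane category at ``wtp``."""
    if result.n == 0:
        raise ValueError("empty PSA result")
    dc = result.draws["delta_cost"].to_numpy()
    dq = result.draws["delta_qaly"].to_numpy()
    indiff = (dc == 0) & (dq == 0)
    dominant = (dc <= 0) & (dq >= 0) & ~indiff
    dominated = (dc >= 0) & (dq <= 0) & ~indiff
    ne = (dc > 0) & (dq > 0)
    sw = (dc < 0) & (dq < 0)
    ne_below = ne & (dc < wtp * dq)
    n = result.n
    return IceSummary(
        wtp=wtp,
        dominant=dominant.mean(),
        ne_below_wtp=ne_below.mean(),
        ne_above_wtp=(ne & ~ne_below).mean(),
        sw=sw.mean(),
        dominated=(dominated | indiff).mean(),
        n=n,
    )


def ceac(result: PSAResult, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    For each WTP the curve reports the fraction of draws with strictly
    positive incremental net monetary benefit.  The curve need not be
    monotone when dominance quadrants mix.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if result.n == 0 or wtp_grid.size == 0 or (wtp_grid < 0).any():
        raise ValueError("need a non-empty result and a non-negative WTP grid")
    dc = result.draws["delta_cost"].to_numpy()
    dq = result.draws["delta_qaly"].to_numpy()
    prob = [( wtp * dq - dc > 0).mean() for wtp in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "p_cost_effective": prob})
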