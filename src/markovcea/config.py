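"""Analysis configuration: schema, validation, and file I/O.

A configuration file (YAML, or JSON — YAML is a superset here) carries
everything one analysis needs: the model conventions, exactly two
treatment strategies, the deterministic sensitivity bounds, the PSA
distributions, the synthetic-cohort block, and a seed.  Validation is
eager and names the offending field; the nested domain types re-check
their own invariants on construction, so a config that loads is a config
that runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import pydantic
import yaml

from . import ipd
from .cea import TwoArmModel
from .dsa import ParameterSpec
from .errors import ConfigError
from .model import Correction, DiscountTiming, ModelConfig, StrategyInputs
from .psa import DistributionFamily, ParameterDistribution

__all__ = ["AnalysisConfig", "load_config", "save_config"]


class _Base(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class ModelBlock(_Base):
    horizon_cycles: int = 120
    cycle_length_years: float = 1.0 / 12.0
    annual_discount_rate: float = 0.035
    correction: Literal["within_cycle", "none", "start"] = "within_cycle"
    discount_timing: Literal["cycle_start", "cycle_mid", "cycle_end"] = "cycle_mid"
    discount_life_years: bool = True
    wtp_very_cost_effective: float = 192_050.0
    wtp_cost_effective: float = 576_150.0

    def to_domain(self) -> ModelConfig:
        return ModelConfig(
            horizon_cycles=self.horizon_cycles,
            cycle_length_years=self.cycle_length_years,
            annual_discount_rate=self.annual_discount_rate,
            correction=Correction(self.correction),
            discount_timing=DiscountTiming(self.discount_timing),
            discount_life_years=self.discount_life_years,
            wtp_very_cost_effective=self.wtp_very_cost_effective,
            wtp_cost_effective=self.wtp_cost_effective,
        )


class StrategyBlock(_Base):
    name: str
    cost_pfs_month: float = pydantic.Field(ge=0)
    cost_pd_month: float = pydantic.Field(ge=0)
    utility_pfs: float = pydantic.Field(ge=0, le=1)
    utility_pd: float = pydantic.Field(ge=0, le=1)
    p_pfs_to_pd: float = pydantic.Field(ge=0, le=1)
    p_pfs_to_death: float = pydantic.Field(ge=0, le=1)
    p_pd_to_death: float = pydantic.Field(ge=0, le=1)

    def to_domain(self) -> StrategyInputs:
        return StrategyInputs(**self.model_dump())


class DSABlock(_Base):
    id: str
    arm: Literal["intervention", "comparator", "both", "config"]
    field: str
    base_value: float
    lower_bound: float
    upper_bound: float
    bound_source: str = ""

    def to_domain(self) -> ParameterSpec:
        return ParameterSpec(**self.model_dump())


class PSABlock(_Base):
    id: str
    arm: Literal["intervention", "comparator", "both"]
    field: str
    family: Literal["gamma", "beta"]
    mean: float
    sd: float

    def to_domain(self) -> ParameterDistribution:
        return ParameterDistribution(
            id=self.id,
            arm=self.arm,
            field=self.field,
            family=DistributionFamily(self.family),
            mean=self.mean,
            sd=self.sd,
        )


class SyntheticBlock(_Base):
    n_patients: int = pydantic.Field(ge=1)
    r_pfs_to_pd: float = pydantic.Field(ge=0)
    r_pfs_to_death: float = pydantic.Field(ge=0)
    r_pd_to_death: float = pydantic.Field(ge=0)
    cost_pfs_mean: float = pydantic.Field(ge=0)
    cost_pfs_sd: float = pydantic.Field(ge=0)
    cost_pd_mean: float = pydantic.Field(ge=0)
    cost_pd_sd: float = pydantic.Field(ge=0)
    followup_years: float = pydantic.Field(gt=0)
    dropout_rate: float = pydantic.Field(default=0.0, ge=0)

    def to_domain(self, seed: int) -> ipd.TrueCohortParameters:
        return ipd.TrueCohortParameters(
            n_patients=self.n_patients,
            r_pfs_to_pd=self.r_pfs_to_pd,
            r_pfs_to_death=self.r_pfs_to_death,
            r_pd_to_death=self.r_pd_to_death,
            cost_pfs=ipd.CostModel(self.cost_pfs_mean, self.cost_pfs_sd),
            cost_pd=ipd.CostModel(self.cost_pd_mean, self.cost_pd_sd),
            followup_years=self.followup_years,
            dropout_rate=self.dropout_rate,
            seed=seed,
        )


class AnalysisConfig(_Base):
    """Top-level, schema-validated analysis configuration."""

    name: str = "analysis"
    seed: int = 20201
    currency: str = "QAR"
    usd_to_qar: float = 3.65
    model: ModelBlock = ModelBlock()
    intervention: StrategyBlock
    comparator: StrategyBlock
    dsa: list[DSABlock] = []
    psa: list[PSABlock] = []
    psa_draws: int = 10_000
    synthetic: SyntheticBlock | None = None

    @pydantic.model_validator(mode="after")
    def _domain_invariants(self) -> "AnalysisConfig":
        # Constructing the domain objects runs their full invariant checks.
        try:
            self.two_arm_model()
            for d in self.dsa:
                d.to_domain()
            for p in self.psa:
                p.to_domain()
        except (ValueError, ConfigError) as exc:
            raise ValueError(str(exc)) from exc
        ids = [d.id for d in self.dsa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dsa parameter ids")
        ids = [p.id for p in self.psa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate psa parameter ids")
        return self

    def two_arm_model(self) -> TwoArmModel:
        return TwoArmModel(
            intervention=self.intervention.to_domain(),
            comparator=self.comparator.to_domain(),
            config=self.model.to_domain(),
        )

    def dsa_specs(self) -> list[ParameterSpec]:
        return [d.to_domain() for d in self.dsa]

    def psa_distributions(self) -> list[ParameterDistribution]:
        return [p.to_domain() for p in self.psa]

    def synthetic_parameters(self, seed: int | None = None) -> ipd.TrueCohortParameters:
        if self.synthetic is None:
            raise ConfigError("configuration has no 'synthetic' block")
        return self.synthetic.to_domain(self.seed if seed is None else seed)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse and validate a YAML/JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return AnalysisConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips exactly)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
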