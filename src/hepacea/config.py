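"""Run configuration: one validated object driving every pipeline stage."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .cohort import CostTiming
from .errors import ConfigError
from .model import CostUtilityModel
from .parameters import DiscountSpec, PaperFixture, load_paper_fixture


class PSASettings(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int = Field(default=10_000, ge=1)
    seed: int = Field(default=0, ge=0)
    grid_points: int = Field(default=101, ge=2)


class RunConfig(BaseModel):
    """Settings for a model run; unset fields fall back to the parameter file."""

    model_config = ConfigDict(frozen=True)

    parameter_file: Path | None = None
    horizon: int | None = Field(default=None, ge=1)
    discount_mode: Literal["paper_one_time", "per_cycle"] | None = None
    annual_rate: float | None = Field(default=None, ge=0.0, lt=1.0)
    half_cycle: bool = True
    cost_timing: CostTiming = "package"
    tornado_outcome: Literal["nmb_at_threshold", "icer"] = "nmb_at_threshold"
    interval_rule: Literal["central95", "uniform"] = "central95"
    psa: PSASettings = PSASettings()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            return cls(**raw)
        except ValidationError as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def load_fixture(self) -> PaperFixture:
        if self.parameter_file is not None and not Path(self.parameter_file).exists():
            raise ConfigError(f"parameter file not found: {self.parameter_file}")
        return load_paper_fixture(self.parameter_file)

    def build_model(self, fixture: PaperFixture | None = None) -> CostUtilityModel:
        fixture = fixture or self.load_fixture()
        discount = fixture.discount
        if self.discount_mode is not None or self.annual_rate is not None:
            discount = DiscountSpec(
                annual_rate=self.annual_rate if self.annual_rate is not None else discount.annual_rate,
                mode=self.discount_mode or discount.mode,
            )
        return CostUtilityModel(
            reference=fixture.reference,
            alternative=fixture.alternative,
            wtp=fixture.wtp,
            horizon=self.horizon or fixture.horizon_cycles,
            discount=discount,
            half_cycle=self.half_cycle,
            cost_timing=self.cost_timing,
        )

    def content_hash(self) -> str:
        """Stable digest of the configuration, for output provenance."""
        payload = self.model_dump(mode="json")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
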