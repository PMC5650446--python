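"""Model parameter space for the proton-vs-SBRT cost-utility model.

Holds the published base-case inputs (monthly transition probabilities,
state utilities, discounted state costs, grade >=3 toxicity), derives
monthly transition probabilities from median times-to-event, applies
discounting, and constructs the +/-30% sensitivity ranges and the
willingness-to-pay threshold (3x per-capita GDP).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ParameterError

#: Ordered health states of the cohort model; ``dead`` is absorbing.
HEALTH_STATES: tuple[str, str, str] = ("stable", "progressive", "dead")


class StrategyDefinition(BaseModel):
    """One treatment arm: monthly transitions, utilities, costs, toxicity.

    Utilities are annual QALY weights in [0, 1]; costs are NT$ under the
    arm's accounting convention (stable-stage treatment package,
    progressive-stage cost per month of occupancy).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    p_stable_to_prog: float = Field(ge=0.0, le=1.0)
    p_stable_to_dead: float = Field(ge=0.0, le=1.0)
    p_prog_to_dead: float = Field(ge=0.0, le=1.0)
    u_stable: float = Field(ge=0.0, le=1.0)
    u_prog: float = Field(ge=0.0, le=1.0)
    c_stable: float = Field(ge=0.0)
    c_prog: float = Field(ge=0.0)
    tox_incidence: float = Field(default=0.0, ge=0.0, le=1.0)
    tox_cost: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _stable_row_feasible(self) -> "StrategyDefinition":
        if self.p_stable_to_prog + self.p_stable_to_dead > 1.0 + 1e-12:
            raise ValueError(
                "stable-state exit probabilities exceed 1: "
                f"{self.p_stable_to_prog} + {self.p_stable_to_dead}"
            )
        return self


class ParameterRange(BaseModel):
    """Base value with low/high sensitivity bounds and a distribution family."""

    model_config = ConfigDict(frozen=True)

    base: float
    low: float
    high: float
    family: Literal["beta", "lognormal", "constant"] = "constant"

    @model_validator(mode="after")
    def _ordered_and_supported(self) -> "ParameterRange":
        if not self.low <= self.base <= self.high:
            raise ValueError(f"require low <= base <= high, got {self.low}, {self.base}, {self.high}")
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError("beta family requires the range to lie in [0, 1]")
        return self

    @property
    def width(self) -> float:
        return self.high - self.low


class DiscountSpec(BaseModel):
    """Discounting convention.

    ``paper_one_time`` applies a single (1 - rate) reduction to costs, the
    convention that links the undiscounted billing subtotals to the
    discounted base estimates; ``per_cycle`` applies the standard
    exponential factor (1 + rate)^(-cycle/12) inside the cohort engine.
    """

    model_config = ConfigDict(frozen=True)

    annual_rate: float = Field(default=0.03, ge=0.0, lt=1.0)
    mode: Literal["paper_one_time", "per_cycle"] = "paper_one_time"

    def cycle_factor(self, cycle: float) -> float:
        """Discount factor for a contribution accrued at month ``cycle``."""
        if self.mode != "per_cycle":
            return 1.0
        return (1.0 + self.annual_rate) ** (-cycle / 12.0)


class WTPSpec(BaseModel):
    """Willingness-to-pay threshold as a multiple of per-capita GDP."""

    model_config = ConfigDict(frozen=True)

    gdp_per_capita: int = Field(gt=0)
    multiplier: int = Field(default=3, ge=1)

    @property
    def threshold(self) -> int:
        return self.gdp_per_capita * self.multiplier


class CostBreakdown(BaseModel):
    """Undiscounted billing components of one arm, with the printed subtotals.

    Printed subtotals are kept verbatim even where they disagree with the
    component sums; :func:`audit_fixture` flags such rows.
    """

    model_config = ConfigDict(frozen=True)

    treatment: float
    stable_lab: float
    prog_lab: float
    prog_tox: float
    printed_subtotal_stable: float
    printed_subtotal_prog: float
    printed_total: float

    @property
    def computed_subtotal_stable(self) -> float:
        return self.treatment + self.stable_lab

    @property
    def computed_subtotal_prog(self) -> float:
        return self.prog_lab + self.prog_tox


def monthly_prob_from_median(median_months: float) -> float:
    """Constant monthly event probability implied by a median time-to-event.

    Uses P(1 month) = 1 - 0.5^(1/median): the per-cycle probability under
    which half of a cohort has had the event after ``median_months`` cycles.
    """
    if not (isinstance(median_months, (int, float)) and math.isfinite(median_months)):
        raise ParameterError(f"median must be a finite number, got {median_months!r}")
    if median_months <= 0:
        raise ParameterError(f"median must be positive, got {median_months}")
    return 1.0 - 0.5 ** (1.0 / median_months)


def median_from_monthly_prob(p: float) -> float:
    """Median time-to-event (months) implied by a constant monthly probability.

    Inverse of :func:`monthly_prob_from_median`: m = ln(0.5) / ln(1 - p).
    """
    if not (isinstance(p, (int, float)) and math.isfinite(p) and 0.0 < p < 1.0):
        raise ParameterError(f"monthly probability must lie in (0, 1), got {p!r}")
    return math.log(0.5) / math.log(1.0 - p)


def apply_discount(value: float, spec: DiscountSpec, *, round_currency: bool = True) -> float:
    """One-time discount of a cost, reproducing the discounted base estimates.

    Only meaningful for ``mode='paper_one_time'``; under ``per_cycle`` the
    engine applies :meth:`DiscountSpec.cycle_factor` instead and the value
    is returned unchanged here.
    """
    if value < 0:
        raise ParameterError(f"cost must be nonnegative, got {value}")
    if spec.mode != "paper_one_time":
        return value
    discounted = value * (1.0 - spec.annual_rate)
    return float(round(discounted)) if round_currency else discounted


def build_sensitivity_range(
    base: float,
    fraction: float = 0.30,
    family: Literal["beta", "lognormal", "constant"] = "constant",
    *,
    ndigits: int | None = None,
) -> ParameterRange:
    """Symmetric +/-`fraction` range around ``base``.

    ``ndigits`` rounds the bounds to the base value's printed precision
    (0 for NT$ amounts) so recomputed ranges can be compared cell-for-cell
    with published tables.
    """
    if base < 0:
        raise ParameterError(f"base must be nonnegative, got {base}")
    if not 0.0 < fraction < 1.0:
        raise ParameterError(f"fraction must lie in (0, 1), got {fraction}")
    low = base * (1.0 - fraction)
    high = base * (1.0 + fraction)
    if ndigits is not None:
        low, high = round(low, ndigits), round(high, ndigits)
        if ndigits <= 0:
            low, high = float(low), float(high)
    return ParameterRange(base=base, low=low, high=high, family=family)


def make_wtp_threshold(gdp: int, multiplier: int = 3) -> WTPSpec:
    """WTP threshold at ``multiplier`` x per-capita GDP (integer arithmetic)."""
    return WTPSpec(gdp_per_capita=gdp, multiplier=multiplier)


class PaperFixture(BaseModel):
    """The shipped base-case parameterisation: two arms, ranges, settings."""

    model_config = ConfigDict(frozen=True)

    strategies: dict[str, StrategyDefinition]
    cost_breakdowns: dict[str, CostBreakdown]
    ranges: dict[str, ParameterRange]
    wtp: WTPSpec
    horizon_cycles: int
    discount: DiscountSpec
    sensitivity_fraction: float

    @property
    def reference(self) -> StrategyDefinition:
        return self.strategies["sbrt"]

    @property
    def alternative(self) -> StrategyDefinition:
        return self.strategies["proton"]


def _fixture_path() -> Path:
    return Path(str(resources.files("hepacea").joinpath("data/tables.yaml")))


def load_paper_fixture(path: str | Path | None = None) -> PaperFixture:
    """Load the shipped (or a user-supplied) parameter file.

    The file reproduces the published input tables verbatim, including
    printed subtotals and printed sensitivity bounds; run
    :func:`audit_fixture` for a component-sum consistency report.
    """
    path = Path(path) if path is not None else _fixture_path()
    try:
        raw = yaml.safe_load(path.read_text())
        settings = raw["settings"]
        strategies: dict[str, StrategyDefinition] = {}
        breakdowns: dict[str, CostBreakdown] = {}
        for name, block in raw["strategies"].items():
            strategies[name] = StrategyDefinition(
                name=name,
                p_stable_to_prog=block["transitions"]["stable_to_progressive"],
                p_stable_to_dead=block["transitions"]["stable_to_dead"],
                p_prog_to_dead=block["transitions"]["progressive_to_dead"],
                u_stable=block["utilities"]["stable"],
                u_prog=block["utilities"]["progressive"],
                c_stable=block["costs"]["stable"],
                c_prog=block["costs"]["progressive"],
                tox_incidence=block["toxicity"]["incidence"],
                tox_cost=block["toxicity"]["cost"],
            )
            breakdowns[name] = CostBreakdown(**block["cost_components"])
        ranges = {key: ParameterRange(**spec) for key, spec in raw["ranges"].items()}
        return PaperFixture(
            strategies=strategies,
            cost_breakdowns=breakdowns,
            ranges=ranges,
            wtp=WTPSpec(**settings["wtp"]),
            horizon_cycles=settings["horizon_cycles"],
            discount=DiscountSpec(
                annual_rate=settings["annual_discount_rate"],
                mode=settings.get("discount_mode", "paper_one_time"),
            ),
            sensitivity_fraction=settings["sensitivity_fraction"],
        )
    except (OSError, KeyError, TypeError, yaml.YAMLError) as exc:
        raise IOError(f"malformed or unreadable parameter file {path}: {exc}") from exc


def _printed_decimals(x: float) -> int:
    """Number of decimal places in a value's shortest decimal representation."""
    text = repr(float(x))
    if "e" in text or "." not in text:
        return 0
    return len(text.split(".")[1].rstrip("0"))


def audit_fixture(fixture: PaperFixture) -> pd.DataFrame:
    """Consistency report comparing printed cells with recomputed values.

    Checks, per arm: billing subtotals against component sums, totals
    against subtotals, the discount link (discounted base estimate =
    undiscounted subtotal x (1 - rate), rounded to NT$), and every
    sensitivity bound against base x (1 -/+ fraction) at the printed
    precision (a one-ulp tolerance absorbs round-versus-truncate
    ambiguity in the published cells).

    Returns a frame with columns (parameter, printed, recomputed, delta,
    flag); ``flag`` is True where the printed cell is inconsistent.
    """
    rows: list[dict] = []

    def check(parameter: str, printed: float, recomputed: float, tol: float) -> None:
        delta = printed - recomputed
        rows.append(
            {
                "parameter": parameter,
                "printed": printed,
                "recomputed": recomputed,
                "delta": delta,
                "flag": abs(delta) > tol,
            }
        )

    for name, bd in fixture.cost_breakdowns.items():
        check(f"{name}.subtotal_stable", bd.printed_subtotal_stable, bd.computed_subtotal_stable, 0.5)
        check(f"{name}.subtotal_prog", bd.printed_subtotal_prog, bd.computed_subtotal_prog, 0.5)
        check(
            f"{name}.total",
            bd.printed_total,
            bd.printed_subtotal_stable + bd.printed_subtotal_prog,
            0.5,
        )
        strategy = fixture.strategies[name]
        rate = fixture.discount.annual_rate
        check(f"{name}.c_stable_discount", strategy.c_stable, round(bd.printed_subtotal_stable * (1 - rate)), 0.5)
        check(f"{name}.c_prog_discount", strategy.c_prog, round(bd.printed_subtotal_prog * (1 - rate)), 0.5)

    f = fixture.sensitivity_fraction
    for key, rng in fixture.ranges.items():
        for side, printed, factor in (("low", rng.low, 1 - f), ("high", rng.high, 1 + f)):
            nd = _printed_decimals(printed)
            ulp = 10.0 ** (-nd)
            check(f"{key}.{side}", printed, round(rng.base * factor, nd), 1.01 * ulp)

    return pd.DataFrame(rows, columns=["parameter", "printed", "recomputed", "delta", "flag"])
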