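"""Full cost-utility pipeline: strategies -> traces -> accrual -> comparison.

``CostUtilityModel`` is the object the sensitivity analyses rerun: it owns
the two treatment arms plus the run settings, evaluates the base case, and
supports pinning any named parameter to an alternative value via dotted
identifiers like ``"proton.u_stable"`` or ``"sbrt.p_prog_to_dead"``.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import cea, cohort
from .cohort import CostTiming
from .errors import ConfigError
from .parameters import DiscountSpec, PaperFixture, StrategyDefinition, WTPSpec

#: Strategy fields that sensitivity analyses may override.
OVERRIDABLE_FIELDS = (
    "p_stable_to_prog",
    "p_stable_to_dead",
    "p_prog_to_dead",
    "u_stable",
    "u_prog",
    "c_stable",
    "c_prog",
    "tox_incidence",
    "tox_cost",
)


@dataclass(frozen=True)
class BaseCaseResult:
    """Per-arm outcomes plus the incremental comparison and NMB at threshold."""

    reference: cea.StrategyOutcome
    alternative: cea.StrategyOutcome
    comparison: cea.ComparisonResult
    nmb_at_threshold: float

    def to_dict(self) -> dict:
        out = self.comparison.to_dict()
        out.update(
            {
                "cost_ref": self.reference.cost,
                "effect_ref": self.reference.effect,
                "cost_alt": self.alternative.cost,
                "effect_alt": self.alternative.effect,
                "nmb_at_threshold": self.nmb_at_threshold,
            }
        )
        return out


class CostUtilityModel:
    """Two-arm Markov cost-utility model with fixed run settings."""

    def __init__(
        self,
        reference: StrategyDefinition,
        alternative: StrategyDefinition,
        wtp: WTPSpec,
        horizon: int = 60,
        discount: DiscountSpec | None = None,
        half_cycle: bool = True,
        cost_timing: CostTiming = "package",
    ) -> None:
        self.reference = reference
        self.alternative = alternative
        self.wtp = wtp
        self.horizon = horizon
        self.discount = discount or DiscountSpec()
        self.half_cycle = half_cycle
        self.cost_timing = cost_timing

    @classmethod
    def from_fixture(cls, fixture: PaperFixture, **settings) -> "CostUtilityModel":
        return cls(
            reference=fixture.reference,
            alternative=fixture.alternative,
            wtp=fixture.wtp,
            horizon=fixture.horizon_cycles,
            discount=fixture.discount,
            **settings,
        )

    # -- parameter plumbing -------------------------------------------------

    def parameter_value(self, parameter_id: str) -> float:
        strategy, field = self._resolve(parameter_id)
        return getattr(strategy, field)

    def _resolve(self, parameter_id: str) -> tuple[StrategyDefinition, str]:
        try:
            strategy_name, field = parameter_id.split(".", 1)
        except ValueError:
            raise ConfigError(f"parameter id {parameter_id!r} is not 'strategy.field'")
        by_name = {self.reference.name: self.reference, self.alternative.name: self.alternative}
        if strategy_name not in by_name:
            raise ConfigError(f"unknown strategy {strategy_name!r} in {parameter_id!r}")
        if field not in OVERRIDABLE_FIELDS:
            raise ConfigError(f"unknown parameter field {field!r} in {parameter_id!r}")
        return by_name[strategy_name], field

    def with_overrides(self, overrides: dict[str, float]) -> "CostUtilityModel":
        """A copy of the model with the given parameters pinned."""
        updates: dict[str, dict[str, float]] = {}
        for parameter_id, value in overrides.items():
            strategy, field = self._resolve(parameter_id)
            updates.setdefault(strategy.name, {})[field] = value
        new = {"reference": self.reference, "alternative": self.alternative}
        for role in ("reference", "alternative"):
            strategy = new[role]
            if strategy.name in updates:
                new[role] = strategy.model_copy(update=updates[strategy.name])
        clone = CostUtilityModel(
            reference=new["reference"],
            alternative=new["alternative"],
            wtp=self.wtp,
            horizon=self.horizon,
            discount=self.discount,
            half_cycle=self.half_cycle,
            cost_timing=self.cost_timing,
        )
        return clone

    # -- evaluation ---------------------------------------------------------

    def trace(self, strategy: StrategyDefinition) -> cohort.CohortTrace:
        return cohort.run_cohort(cohort.build_transition_matrix(strategy), self.horizon)

    def outcome(self, strategy: StrategyDefinition) -> cea.StrategyOutcome:
        accrual = cohort.accrue(
            self.trace(strategy),
            strategy,
            discount=self.discount,
            half_cycle=self.half_cycle,
            cost_timing=self.cost_timing,
        )
        return cea.StrategyOutcome(
            name=strategy.name, cost=accrual.total_cost, effect=accrual.total_qalys
        )

    def base_case(self) -> BaseCaseResult:
        ref = self.outcome(self.reference)
        alt = self.outcome(self.alternative)
        comparison = cea.compare(ref, alt)
        return BaseCaseResult(
            reference=ref,
            alternative=alt,
            comparison=comparison,
            nmb_at_threshold=cea.nmb(
                comparison.delta_effect, comparison.delta_cost, self.wtp.threshold
            ),
        )

    def evaluate(
        self,
        overrides: dict[str, float] | None = None,
        outcome: str = "nmb_at_threshold",
    ) -> float:
        """Scalar outcome of the full pipeline under optional overrides.

        ``outcome`` is ``"nmb_at_threshold"`` (default; defined for every
        input) or ``"icer"`` (undefined when the arms are equally
        effective, in which case a ConfigError is raised).
        """
        model = self.with_overrides(overrides) if overrides else self
        result = model.base_case()
        if outcome == "nmb_at_threshold":
            return result.nmb_at_threshold
        if outcome == "icer":
            if result.comparison.icer is None:
                raise ConfigError("ICER undefined: the arms are equally effective")
            return result.comparison.icer
        raise ConfigError(f"unknown outcome {outcome!r}")
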