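"""Cost-effectiveness statistics: ICER, dominance, net monetary benefit.

Comparisons are incremental, alternative minus reference (here: proton
beam therapy minus SBRT). The ICER is the extra cost per QALY gained; the
net monetary benefit at willingness-to-pay lambda is NMB = dE*lambda - dC,
positive when the alternative is worth its extra cost at that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ParameterError

Dominance = Literal["dominant", "dominated", "trade-off"]


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted total cost (NT$) and effect (QALYs) of one arm."""

    name: str
    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.effect < 0:
            raise ParameterError(f"cost and effect must be nonnegative for {self.name!r}")


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental comparison of an alternative against a reference arm."""

    reference: str
    alternative: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: Dominance

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "alternative": self.alternative,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "dominance": self.dominance,
        }


def _classify(delta_cost: float, delta_effect: float) -> Dominance:
    if (delta_effect > 0 and delta_cost <= 0) or (delta_effect >= 0 and delta_cost < 0):
        return "dominant"
    if (delta_effect < 0 and delta_cost >= 0) or (delta_effect <= 0 and delta_cost > 0):
        return "dominated"
    return "trade-off"


def compare(reference: StrategyOutcome, alternative: StrategyOutcome) -> ComparisonResult:
    """Incremental cost, incremental effect, ICER and dominance status.

    The ICER is left undefined (None) when the strategies are equally
    effective — no division is attempted.
    """
    delta_cost = alternative.cost - reference.cost
    delta_effect = alternative.effect - reference.effect
    icer = delta_cost / delta_effect if delta_effect != 0 else None
    return ComparisonResult(
        reference=reference.name,
        alternative=alternative.name,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=_classify(delta_cost, delta_effect),
    )


def nmb(delta_effect: float, delta_cost: float, wtp: float) -> float:
    """Incremental net monetary benefit dE*lambda - dC at threshold ``wtp``."""
    if wtp < 0:
        raise ParameterError(f"willingness-to-pay must be nonnegative, got {wtp}")
    return delta_effect * wtp - delta_cost


@dataclass(frozen=True)
class NMBCurve:
    """Per-strategy and incremental NMB over an evenly spaced lambda grid."""

    wtp_grid: np.ndarray
    nmb_reference: np.ndarray
    nmb_alternative: np.ndarray
    incremental_nmb: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.wtp_grid,
                "nmb_ref": self.nmb_reference,
                "nmb_alt": self.nmb_alternative,
                "incremental_nmb": self.incremental_nmb,
            }
        )


def nmb_curve(
    reference: StrategyOutcome,
    alternative: StrategyOutcome,
    threshold: float,
    grid_points: int = 101,
) -> NMBCurve:
    """NMB as a function of willingness-to-pay from 0 to ``threshold``.

    The incremental curve is affine in lambda with slope dE and intercept
    -dC, so it crosses zero exactly at the ICER whenever the ICER lies
    inside the grid.
    """
    if grid_points < 2:
        raise ParameterError(f"grid must have at least 2 points, got {grid_points}")
    grid = np.linspace(0.0, threshold, grid_points)
    nmb_ref = reference.effect * grid - reference.cost
    nmb_alt = alternative.effect * grid - alternative.cost
    return NMBCurve(
        wtp_grid=grid,
        nmb_reference=nmb_ref,
        nmb_alternative=nmb_alt,
        incremental_nmb=nmb_alt - nmb_ref,
    )
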