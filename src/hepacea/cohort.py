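"""Markov cohort engine: transition matrix, trace, survival, accrual.

The cohort moves through three states (stable disease, progressive
disease, dead) in monthly cycles over a 5-year (60-cycle) horizon. No
backward transitions exist and death is absorbing; background (non-cancer)
mortality is excluded. QALYs and costs are accrued per cycle with an
optional life-table half-cycle correction and either a one-time or a
per-cycle discounting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import MedianNotReachedError, ParameterError
from .parameters import HEALTH_STATES, DiscountSpec, StrategyDefinition

STABLE, PROGRESSIVE, DEAD = range(3)

#: How state costs are charged over time.
#:   package   - stable-state cost once on entry (a treatment package),
#:               progressive-state cost per month of occupancy (default);
#:   per_cycle - both costs per month of state occupancy;
#:   one_time  - both costs once on entry into the state.
CostTiming = Literal["package", "per_cycle", "one_time"]


def build_transition_matrix(s: StrategyDefinition) -> np.ndarray:
    """Monthly 3x3 transition matrix in (stable, progressive, dead) order."""
    p_stay_stable = 1.0 - s.p_stable_to_prog - s.p_stable_to_dead
    if p_stay_stable < -1e-12:
        raise ParameterError(
            f"stable-state exit probabilities sum above 1 for {s.name!r}"
        )
    m = np.array(
        [
            [max(p_stay_stable, 0.0), s.p_stable_to_prog, s.p_stable_to_dead],
            [0.0, 1.0 - s.p_prog_to_dead, s.p_prog_to_dead],
            [0.0, 0.0, 1.0],
        ]
    )
    return m


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions at each cycle boundary 0..horizon."""

    occupancy: np.ndarray  # shape (horizon + 1, 3)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def survival(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD]

    def to_frame(self, discount: DiscountSpec | None = None) -> pd.DataFrame:
        cycles = np.arange(self.horizon + 1)
        frame = pd.DataFrame(self.occupancy, columns=list(HEALTH_STATES))
        frame.insert(0, "cycle", cycles)
        frame["survival"] = self.survival
        if discount is not None:
            frame["discount_factor"] = [discount.cycle_factor(t) for t in cycles]
        return frame


def run_cohort(
    m: np.ndarray,
    horizon: int = 60,
    start: np.ndarray | None = None,
) -> CohortTrace:
    """Iterate the cohort for ``horizon`` monthly cycles from ``start``.

    The cycle-t occupancy equals ``start @ m**t``; the whole cohort starts
    in the stable state by default.
    """
    if horizon < 1:
        raise ParameterError(f"horizon must be at least 1 cycle, got {horizon}")
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ParameterError("transition matrix must be 3x3 with unit row sums")
    occ = np.array([1.0, 0.0, 0.0]) if start is None else np.asarray(start, dtype=float)
    if occ.shape != (3,) or occ.min() < 0 or abs(occ.sum() - 1.0) > 1e-9:
        raise ParameterError("start occupancy must be a 3-vector summing to 1")
    trace = np.empty((horizon + 1, 3))
    trace[0] = occ
    for t in range(1, horizon + 1):
        occ = occ @ m
        trace[t] = occ
    return CohortTrace(occupancy=trace)


def survival_curve(trace: CohortTrace) -> np.ndarray:
    """Fraction alive (1 - dead) at each cycle boundary; nonincreasing."""
    return trace.survival


def median_survival(trace: CohortTrace) -> float:
    """Modeled median overall survival in months, linearly interpolated.

    Finds the first cycle at which survival drops below 0.5 and
    interpolates between the bracketing cycle boundaries. Raises
    :class:`MedianNotReachedError` if survival stays at or above 0.5
    throughout the horizon. Round the result to the nearest whole month to
    compare with integer-month summaries.
    """
    surv = trace.survival
    below = np.nonzero(surv < 0.5)[0]
    if below.size == 0:
        raise MedianNotReachedError(
            f"survival is {surv[-1]:.4f} at the {trace.horizon}-cycle horizon"
        )
    i = int(below[0])
    if i == 0:
        return 0.0
    s0, s1 = surv[i - 1], surv[i]
    return (i - 1) + (s0 - 0.5) / (s0 - s1)


@dataclass(frozen=True)
class AccrualResult:
    """Discounted totals and the per-cycle ledger behind them."""

    total_cost: float
    total_qalys: float
    life_years: float
    ledger: pd.DataFrame = field(repr=False)

    def summary(self) -> dict[str, float]:
        return {
            "total_cost": self.total_cost,
            "total_qalys": self.total_qalys,
            "life_years": self.life_years,
        }


def accrue(
    trace: CohortTrace,
    s: StrategyDefinition,
    discount: DiscountSpec | None = None,
    half_cycle: bool = True,
    cost_timing: CostTiming = "package",
    tox_utility_weight: float = 0.0,
) -> AccrualResult:
    """Accrue discounted costs and QALYs over the trace for one arm.

    Per cycle t (1..horizon), state membership is the start-of-cycle
    occupancy, or the mean of the boundary occupancies when ``half_cycle``
    is on (life-table correction). Utilities are annual weights, so each
    month in a state earns u/12 QALYs. ``tox_utility_weight`` optionally
    scales utilities by (1 - incidence * weight) for arms whose published
    utilities are not already toxicity-adjusted; the default of 0 treats
    them as adjusted.

    Costs follow ``cost_timing`` (see :data:`CostTiming`); entry costs are
    charged at the entry cycle. Under a one-time discount convention the
    engine applies no per-cycle factor (costs arrive pre-discounted);
    under ``per_cycle`` mode each cycle's contribution is multiplied by
    (1 + rate)^(-t/12).
    """
    discount = discount or DiscountSpec(annual_rate=0.0)
    occ = trace.occupancy
    horizon = trace.horizon

    tox_scale = 1.0 - s.tox_incidence * tox_utility_weight
    utilities = np.array([s.u_stable * tox_scale, s.u_prog * tox_scale, 0.0])

    cycles = np.arange(1, horizon + 1)
    membership = 0.5 * (occ[:-1] + occ[1:]) if half_cycle else occ[:-1].copy()
    factors = np.array([discount.cycle_factor(t) for t in cycles])

    qaly_per_cycle = (membership @ utilities) / 12.0 * factors
    life_months = membership[:, [STABLE, PROGRESSIVE]].sum(axis=1) * factors

    # Entrants per cycle: the whole starting cohort enters stable at t=0;
    # stable occupants who progress enter the progressive state at t.
    entered_prog = occ[:-1, STABLE] * s.p_stable_to_prog
    entry_factor0 = discount.cycle_factor(0.0)

    if cost_timing == "per_cycle":
        cost_per_cycle = (
            membership[:, STABLE] * s.c_stable + membership[:, PROGRESSIVE] * s.c_prog
        ) * factors
        entry_cost = 0.0
    elif cost_timing == "one_time":
        cost_per_cycle = entered_prog * s.c_prog * factors
        entry_cost = occ[0, STABLE] * s.c_stable * entry_factor0
    elif cost_timing == "package":
        cost_per_cycle = membership[:, PROGRESSIVE] * s.c_prog * factors
        entry_cost = occ[0, STABLE] * s.c_stable * entry_factor0
    else:
        raise ParameterError(f"unknown cost timing {cost_timing!r}")

    ledger = pd.DataFrame(
        {
            "cycle": cycles,
            "stable": membership[:, STABLE],
            "progressive": membership[:, PROGRESSIVE],
            "discount_factor": factors,
            "cost": cost_per_cycle,
            "qalys": qaly_per_cycle,
        }
    )
    return AccrualResult(
        total_cost=float(entry_cost + cost_per_cycle.sum()),
        total_qalys=float(qaly_per_cycle.sum()),
        life_years=float(life_months.sum() / 12.0),
        ledger=ledger,
    )
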