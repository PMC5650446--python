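"""Pseudo individual-level trial data with the structure the model assumes.

The cohort model consumes phase-II trial summaries: median times-to-event,
grade >=3 toxicity incidences (0.30 proton, 0.343 SBRT) and package costs.
This module simulates patient-level data consistent with those summaries —
exponential event times (the continuous counterpart of constant monthly
transition probabilities), Bernoulli toxicity flags, perturbed cost draws,
and monthly patient paths through the 3-state chain — so parameter
derivation, the cohort trace and the PSA can be validated end-to-end by
microsimulation without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cohort import DEAD, PROGRESSIVE, STABLE, build_transition_matrix
from .parameters import StrategyDefinition

LN2 = float(np.log(2.0))


class SyntheticTrialSpec(BaseModel):
    """Summary statistics a simulated single-arm trial should reproduce."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(ge=1)
    median_ttp: float = Field(gt=0)  # months
    median_os: float = Field(gt=0)  # months
    tox_incidence: float = Field(default=0.0, ge=0.0, le=1.0)
    cost_noise: float = Field(default=0.0, ge=0.0)  # coefficient of variation
    seed: int = 0


def simulate_event_times(spec: SyntheticTrialSpec) -> pd.DataFrame:
    """Exponential times-to-progression and times-to-death (months).

    Exponential medians equal ln(2)/rate, so the draws reproduce the
    specified medians in distribution; reproducible by seed.
    """
    rng = np.random.default_rng(spec.seed)
    ttp = rng.exponential(spec.median_ttp / LN2, spec.n_patients)
    ttd = rng.exponential(spec.median_os / LN2, spec.n_patients)
    return pd.DataFrame({"id": np.arange(spec.n_patients), "ttp": ttp, "ttd": ttd})


def simulate_toxicity(n: int, incidence: float, seed: int = 0) -> np.ndarray:
    """Bernoulli grade >=3 toxicity flags at the stated incidence."""
    if not 0.0 <= incidence <= 1.0:
        raise ValueError(f"incidence must lie in [0, 1], got {incidence}")
    rng = np.random.default_rng(seed)
    return rng.random(n) < incidence


def simulate_costs(n: int, base_cost: float, cv: float, seed: int = 0) -> np.ndarray:
    """Log-normally perturbed per-patient cost draws with mean ``base_cost``.

    ``cv`` is the coefficient of variation; cv = 0 returns the base cost
    for every patient.
    """
    if cv == 0.0:
        return np.full(n, float(base_cost))
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    return base_cost * rng.lognormal(-0.5 * sigma2, np.sqrt(sigma2), n)


def simulate_trial(spec: SyntheticTrialSpec, base_cost: float = 0.0) -> pd.DataFrame:
    """Per-patient table (id, ttp, ttd, tox[, cost]) for one simulated arm."""
    table = simulate_event_times(spec)
    table["tox"] = simulate_toxicity(spec.n_patients, spec.tox_incidence, spec.seed + 1)
    if base_cost > 0:
        table["cost"] = simulate_costs(spec.n_patients, base_cost, spec.cost_noise, spec.seed + 2)
    return table


@dataclass(frozen=True)
class PatientPaths:
    """Monthly state indices per patient; shape (n_patients, horizon + 1)."""

    states: np.ndarray
    seed: int

    @property
    def n_patients(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1

    def occupancy(self) -> np.ndarray:
        """Empirical per-cycle state-occupancy fractions, shape (H+1, 3)."""
        counts = np.stack(
            [(self.states == s).mean(axis=0) for s in (STABLE, PROGRESSIVE, DEAD)], axis=1
        )
        return counts

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.states, columns=[f"cycle_{t}" for t in range(self.states.shape[1])]
        )
        frame.insert(0, "id", np.arange(self.n_patients))
        return frame


def simulate_patient_paths(
    s: StrategyDefinition, n: int, horizon: int = 60, seed: int = 0
) -> PatientPaths:
    """Microsimulate ``n`` patients through the monthly 3-state chain.

    Every patient starts stable; each cycle draws the next state from the
    same categorical transition row the cohort trace uses, so the
    empirical occupancy converges to the cohort trace as n grows — the
    module's central oracle for the cohort engine.
    """
    matrix = build_transition_matrix(s)
    cum = matrix.cumsum(axis=1)
    rng = np.random.default_rng(seed)
    states = np.empty((n, horizon + 1), dtype=np.int8)
    states[:, 0] = STABLE
    current = np.zeros(n, dtype=np.intp)
    for t in range(1, horizon + 1):
        u = rng.random(n)
        # inverse-CDF draw against each patient's current transition row
        current = (u[:, None] > cum[current]).sum(axis=1)
        states[:, t] = current
    return PatientPaths(states=states, seed=seed)
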