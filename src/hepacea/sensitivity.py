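"""One-way (tornado) and probabilistic (Monte-Carlo) sensitivity analysis.

The tornado analysis reruns the full pipeline twice per parameter (pinned
at its low then high bound, everything else at base) and ranks parameters
by outcome spread. The PSA jointly samples every uncertain parameter from
its fitted distribution — beta for probabilities and utilities, log-normal
for costs — pushes each sample through the cohort model, and summarises
cost-effectiveness as a CEAC and a mean-incremental-NMB curve over the
willingness-to-pay grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .model import CostUtilityModel
from .parameters import ParameterRange

IntervalRule = Literal["central95", "uniform"]


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution fitted to a parameter's base and bounds."""

    family: str
    mean: float
    sd: float
    dist: object = field(repr=False, compare=False)  # frozen scipy distribution or None

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.dist is None:
            return np.full(size, self.mean)
        return self.dist.rvs(size=size, random_state=rng)


def fit_distribution(rng_spec: ParameterRange, rule: IntervalRule = "central95") -> DistributionSpec:
    """Fit a sampling distribution to a base value and its low/high bounds.

    Under the default ``central95`` rule the bounds are read as a central
    95% interval: the distribution is moment-matched to mean = base and
    sd = (high - low) / (2 * 1.96). The ``uniform`` alternative samples
    uniformly on [low, high] regardless of family. Zero-width ranges (and
    family ``constant``) degenerate to a point mass at the base value.
    """
    base, low, high = rng_spec.base, rng_spec.low, rng_spec.high
    if rng_spec.family == "constant" or high == low:
        return DistributionSpec(family="constant", mean=base, sd=0.0, dist=None)
    if rule == "uniform":
        width = high - low
        return DistributionSpec(
            family="uniform",
            mean=0.5 * (low + high),
            sd=width / np.sqrt(12.0),
            dist=stats.uniform(loc=low, scale=width),
        )
    sd = (high - low) / (2.0 * 1.96)
    if rng_spec.family == "beta":
        if not 0.0 < base < 1.0:
            raise ParameterError(f"beta fit requires base in (0, 1), got {base}")
        var = sd * sd
        if var >= base * (1.0 - base):
            raise ParameterError("range too wide for a beta distribution at this mean")
        nu = base * (1.0 - base) / var - 1.0
        return DistributionSpec(
            family="beta", mean=base, sd=sd, dist=stats.beta(a=base * nu, b=(1.0 - base) * nu)
        )
    if rng_spec.family == "lognormal":
        if base <= 0:
            raise ParameterError(f"lognormal fit requires base > 0, got {base}")
        sigma2 = np.log1p((sd / base) ** 2)
        mu = np.log(base) - 0.5 * sigma2
        return DistributionSpec(
            family="lognormal",
            mean=base,
            sd=sd,
            dist=stats.lognorm(s=np.sqrt(sigma2), scale=np.exp(mu)),
        )
    raise ParameterError(f"unknown distribution family {rng_spec.family!r}")


# -- tornado ----------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    """Outcome of pinning one parameter at its bounds, all else at base."""

    parameter: str
    low_bound: float
    high_bound: float
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)

    @property
    def spread_sq(self) -> float:
        return self.spread**2


def one_way(
    model: CostUtilityModel,
    parameter_id: str,
    rng_spec: ParameterRange,
    outcome: str = "nmb_at_threshold",
) -> TornadoEntry:
    """Rerun the full pipeline with one parameter at its low then high bound."""
    model.parameter_value(parameter_id)  # raises ConfigError on unknown ids
    return TornadoEntry(
        parameter=parameter_id,
        low_bound=rng_spec.low,
        high_bound=rng_spec.high,
        outcome_low=model.evaluate({parameter_id: rng_spec.low}, outcome=outcome),
        outcome_high=model.evaluate({parameter_id: rng_spec.high}, outcome=outcome),
    )


def tornado(
    model: CostUtilityModel,
    ranges: dict[str, ParameterRange],
    outcome: str = "nmb_at_threshold",
) -> pd.DataFrame:
    """One-way analysis over every parameter, ranked by outcome spread.

    Columns follow the conventional tornado-ICER report: the outcome at
    each bound, the spread, its square, each parameter's share of the
    total squared spread (risk %), and the cumulative share down the
    ranking.
    """
    if not ranges:
        raise ParameterError("tornado requires at least one parameter range")
    entries = [one_way(model, pid, rng_spec, outcome=outcome) for pid, rng_spec in ranges.items()]
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    total_sq = sum(e.spread_sq for e in entries)
    frame = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "range_low": [e.low_bound for e in entries],
            "range_high": [e.high_bound for e in entries],
            "outcome_low": [e.outcome_low for e in entries],
            "outcome_high": [e.outcome_high for e in entries],
            "spread": [e.spread for e in entries],
            "spread_sq": [e.spread_sq for e in entries],
        }
    )
    frame["risk_pct"] = frame["spread_sq"] / total_sq if total_sq > 0 else 0.0
    frame["cumul_pct"] = frame["risk_pct"].cumsum()
    return frame


# -- probabilistic sensitivity analysis -------------------------------------


@dataclass(frozen=True)
class PSAResult:
    """Joint Monte-Carlo parameter samples and the per-sample outcomes."""

    n_samples: int
    seed: int
    samples: pd.DataFrame
    cost_ref: np.ndarray
    effect_ref: np.ndarray
    cost_alt: np.ndarray
    effect_alt: np.ndarray
    rejections: int
    reference: str
    alternative: str

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_alt - self.cost_ref

    @property
    def delta_effect(self) -> np.ndarray:
        return self.effect_alt - self.effect_ref

    def to_frame(self) -> pd.DataFrame:
        frame = self.samples.copy()
        frame.insert(0, "sample_id", np.arange(self.n_samples))
        frame["cost_ref"] = self.cost_ref
        frame["effect_ref"] = self.effect_ref
        frame["cost_alt"] = self.cost_alt
        frame["effect_alt"] = self.effect_alt
        return frame

    def metadata(self) -> dict:
        return {
            "n": self.n_samples,
            "seed": self.seed,
            "rejections": self.rejections,
            "reference": self.reference,
            "alternative": self.alternative,
        }


def _sample_parameters(
    model: CostUtilityModel,
    specs: dict[str, DistributionSpec],
    n: int,
    seed: int,
) -> tuple[pd.DataFrame, int]:
    """Independent draws per parameter with joint stable-row rejection.

    Each parameter gets its own deterministic substream (spawned from the
    master seed in sorted-id order). Sampled stable-state exit pairs whose
    probabilities sum above 1 are redrawn jointly; the redraw count is
    reported and a warning is issued above a 1% rejection rate.
    """
    ids = sorted(specs)
    streams = {
        pid: np.random.Generator(np.random.PCG64(child))
        for pid, child in zip(ids, np.random.SeedSequence(seed).spawn(len(ids)))
    }
    draws = {pid: specs[pid].sample(streams[pid], n) for pid in ids}

    rejections = 0
    for strategy in (model.reference.name, model.alternative.name):
        sp, sd = f"{strategy}.p_stable_to_prog", f"{strategy}.p_stable_to_dead"
        if sp not in draws or sd not in draws:
            continue
        bad = draws[sp] + draws[sd] > 1.0
        while bad.any():
            k = int(bad.sum())
            rejections += k
            draws[sp][bad] = specs[sp].sample(streams[sp], k)
            draws[sd][bad] = specs[sd].sample(streams[sd], k)
            bad = draws[sp] + draws[sd] > 1.0
    if rejections > 0.01 * n:
        warnings.warn(
            f"PSA rejected {rejections} stable-row samples out of {n} "
            "(exit probabilities summed above 1)",
            stacklevel=3,
        )
    return pd.DataFrame(draws, columns=ids), rejections


def run_psa(
    model: CostUtilityModel,
    specs: dict[str, DistributionSpec],
    n: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Monte-Carlo PSA: sample every parameter jointly, rerun the model.

    Reproducible given (n, seed): the same pair yields bit-identical
    sample sets and outcomes.
    """
    if n < 1:
        raise ParameterError(f"PSA needs at least one sample, got {n}")
    samples, rejections = _sample_parameters(model, specs, n, seed)
    cost_ref = np.empty(n)
    effect_ref = np.empty(n)
    cost_alt = np.empty(n)
    effect_alt = np.empty(n)
    rows = samples.to_dict("records")
    for i, row in enumerate(rows):
        sampled = model.with_overrides(row)
        ref = sampled.outcome(sampled.reference)
        alt = sampled.outcome(sampled.alternative)
        cost_ref[i], effect_ref[i] = ref.cost, ref.effect
        cost_alt[i], effect_alt[i] = alt.cost, alt.effect
    return PSAResult(
        n_samples=n,
        seed=seed,
        samples=samples,
        cost_ref=cost_ref,
        effect_ref=effect_ref,
        cost_alt=cost_alt,
        effect_alt=effect_alt,
        rejections=rejections,
        reference=model.reference.name,
        alternative=model.alternative.name,
    )


def ceac(psa: PSAResult, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each lambda a strategy is counted cost-effective in the samples
    where its NMB is the higher of the two; exact ties contribute half to
    each arm, so the two probabilities always sum to 1. The mean
    incremental NMB across samples is reported alongside.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if psa.n_samples < 1 or grid.size == 0:
        raise ParameterError("CEAC needs a nonempty PSA and grid")
    # incremental NMB per (sample, lambda)
    inc = psa.delta_effect[:, None] * grid[None, :] - psa.delta_cost[:, None]
    p_alt = (inc > 0).mean(axis=0) + 0.5 * (inc == 0).mean(axis=0)
    return pd.DataFrame(
        {
            "lambda": grid,
            f"p_{psa.reference}": 1.0 - p_alt,
            f"p_{psa.alternative}": p_alt,
            "mean_incremental_nmb": inc.mean(axis=0),
        }
    )


def probability_cost_effective(psa: PSAResult, wtp: float) -> float:
    """P(alternative cost-effective) at a single willingness-to-pay value."""
    return float(ceac(psa, np.array([wtp])).iloc[0][f"p_{psa.alternative}"])


def fit_all(
    ranges: dict[str, ParameterRange], rule: IntervalRule = "central95"
) -> dict[str, DistributionSpec]:
    """Fit a distribution for every parameter range."""
    return {pid: fit_distribution(spec, rule=rule) for pid, spec in ranges.items()}
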