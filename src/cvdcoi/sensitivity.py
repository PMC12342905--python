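"""Generic one-way (tornado) and probabilistic (Monte Carlo) sensitivity analysis.

A model is any callable mapping a parameter dict to a scalar total cost.
One-way analysis swings each parameter alone between its low and high
limits and reports the percentage change from base, ranked by swing.
Probabilistic analysis draws all parameters from their declared
distributions and summarizes the trial totals as median, quartiles
(linear interpolation between order statistics) and range — the
five-number summary the box plots are drawn from.

Parameters are sampled independently from one seeded stream, in spec
order, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Distribution",
    "NormalDist",
    "BetaDist",
    "UniformDist",
    "DirichletDist",
    "ParameterSpec",
    "TornadoEntry",
    "PSAResult",
    "one_way",
    "run_psa",
    "combine_extremes",
    "summarize_trials",
]

ModelFn = Callable[[Mapping[str, float]], float]


class Distribution:
    """Base class for PSA sampling distributions."""

    def sample(self, rng: np.random.Generator) -> float:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class NormalDist(Distribution):
    """Normal(mean, sd), optionally truncated to [lower, upper]."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.lower > self.upper:
            raise ValueError("inverted truncation bounds")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(min(max(self.mean, self.lower), self.upper))
        if math.isinf(self.lower) and math.isinf(self.upper):
            return float(rng.normal(self.mean, self.sd))
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return float(stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, random_state=rng))


@dataclass(frozen=True)
class BetaDist(Distribution):
    a: float
    b: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.a, self.b))


@dataclass(frozen=True)
class UniformDist(Distribution):
    low: float
    high: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class DirichletDist(Distribution):
    """Dirichlet over a probability vector; ``sample`` returns the first
    component (scalar-parameter interface); use ``sample_vector`` for the
    full simplex draw."""

    counts: tuple

    def sample_vector(self, rng: np.random.Generator) -> np.ndarray:
        return rng.dirichlet(np.asarray(self.counts, dtype=float))

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.sample_vector(rng)[0])


@dataclass(frozen=True)
class ParameterSpec:
    """A parameter's base case, one-way limits and PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: Optional[Distribution] = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"parameter {self.name!r}: require low <= base <= high, "
                f"got {self.low}, {self.base}, {self.high}"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of a tornado diagram, in % change from base."""

    name: str
    pct_change_low: float
    pct_change_high: float

    @property
    def swing(self) -> float:
        return abs(self.pct_change_high - self.pct_change_low)


@dataclass(frozen=True)
class PSAResult:
    """Trial totals plus the five-number summary used for box plots."""

    trials: tuple
    median: float
    q25: float
    q75: float
    minimum: float
    maximum: float
    n: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.minimum <= self.q25 <= self.median <= self.q75 <= self.maximum):
            raise ValueError("PSA summary violates min <= q25 <= median <= q75 <= max")


def summarize_trials(trials: Sequence[float], seed: Optional[int] = None) -> PSAResult:
    """Five-number summary with quartiles by linear interpolation."""
    arr = np.asarray(trials, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 trials to summarize")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return PSAResult(
        trials=tuple(arr.tolist()),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n=int(arr.size),
        seed=seed,
    )


def _evaluate(model: ModelFn, params: Mapping[str, float], context: str) -> float:
    try:
        return float(model(params))
    except Exception as exc:
        raise RuntimeError(f"model evaluation failed at {context}: {exc}") from exc


def one_way(model: ModelFn, specs: Sequence[ParameterSpec]) -> list[TornadoEntry]:
    """Vary each parameter alone to its limits; rank entries by swing."""
    base_params = {spec.name: spec.base for spec in specs}
    base = _evaluate(model, base_params, "base case")
    if base == 0:
        raise ValueError("base-case total is zero; percent changes undefined")
    entries = []
    for spec in specs:
        lo_params = dict(base_params)
        lo_params[spec.name] = spec.low
        hi_params = dict(base_params)
        hi_params[spec.name] = spec.high
        lo_total = _evaluate(model, lo_params, f"parameter {spec.name!r} at low")
        hi_total = _evaluate(model, hi_params, f"parameter {spec.name!r} at high")
        entries.append(
            TornadoEntry(
                name=spec.name,
                pct_change_low=(lo_total - base) / base * 100.0,
                pct_change_high=(hi_total - base) / base * 100.0,
            )
        )
    return sorted(entries, key=lambda e: e.swing, reverse=True)


def run_psa(
    model: ModelFn,
    specs: Sequence[ParameterSpec],
    n: int = 1000,
    seed: Optional[int] = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty (default 1000 trials)."""
    if n < 2:
        raise ValueError("PSA requires at least 2 trials")
    missing = [spec.name for spec in specs if spec.distribution is None]
    if missing:
        raise ValueError(f"parameters without a distribution: {missing}")
    rng = np.random.default_rng(seed)
    trials = np.empty(n, dtype=float)
    for i in range(n):
        params = {spec.name: spec.distribution.sample(rng) for spec in specs}
        trials[i] = _evaluate(model, params, f"trial {i}")
    return summarize_trials(trials, seed=seed)


def combine_extremes(
    base_total: float,
    component_bounds: Mapping[str, tuple],
) -> list[TornadoEntry]:
    """Tornado over component-model extremes.

    ``component_bounds`` maps component name → (base, minimum, maximum)
    for that component's modelled cost. Each entry reports the % change in
    the (additive) total when the single component is swapped to its
    minimum/maximum, all others held at base.
    """
    if base_total == 0:
        raise ValueError("base total must be non-zero")
    entries = []
    for name, (base, lo, hi) in component_bounds.items():
        if not lo <= base <= hi:
            raise ValueError(f"component {name!r}: bounds must bracket the base value")
        entries.append(
            TornadoEntry(
                name=name,
                pct_change_low=(lo - base) / base_total * 100.0,
                pct_change_high=(hi - base) / base_total * 100.0,
            )
        )
    return sorted(entries, key=lambda e: e.swing, reverse=True)
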