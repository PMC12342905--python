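"""Post-stroke long-term-care Markov cohort model and vascular-dementia share.

Discharge-destination counts from a stroke audit are row-normalized into a
transition matrix; a closed cohort is propagated through annual cycles;
occupancy of the care-home state accumulates into person-years, which are
costed at a per-person-year unit cost. Transition uncertainty for PSA is
drawn row-wise from Dirichlet distributions with the observed counts as
concentrations (the conjugate posterior under a flat prior).

Cycles are annual with no half-cycle correction; costs accrue at cycle
start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .money import Money
from .sensitivity import PSAResult, summarize_trials

__all__ = [
    "TransitionCounts",
    "TransitionMatrix",
    "MarkovModel",
    "DEFAULT_STATES",
    "counts_to_probabilities",
    "run_cohort",
    "care_home_person_years",
    "stroke_ltc_cost",
    "vad_ltc_cost",
    "sample_transition_matrix",
    "psa_stroke_ltc",
]

#: Default pathway states: discharged home, early-supported discharge /
#: community rehabilitation, institutional care, and absorbing death.
DEFAULT_STATES = ("home", "community", "care_home", "death")

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionCounts:
    """Observed transition counts per (from_state, to_state)."""

    states: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.states), len(self.states)):
            raise ValueError("counts must be square over the state list")
        if (counts < 0).any():
            raise ValueError("transition counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "states", tuple(self.states))

    @classmethod
    def from_csv(cls, path: Union[str, Path], states: Optional[Sequence[str]] = None) -> "TransitionCounts":
        """Read the ``from_state,to_state,count`` interface CSV."""
        frame = pd.read_csv(path)
        if states is None:
            states = sorted(set(frame["from_state"]) | set(frame["to_state"]))
        index = {s: i for i, s in enumerate(states)}
        counts = np.zeros((len(states), len(states)))
        for row in frame.itertuples(index=False):
            counts[index[row.from_state], index[row.to_state]] += row.count
        return cls(tuple(states), counts)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probabilities over named states."""

    states: tuple
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.shape != (len(self.states), len(self.states)):
            raise ValueError("probability matrix must be square over the state list")
        if (probs < -_ROW_TOL).any() or (probs > 1 + _ROW_TOL).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = probs.sum(axis=1)
        if np.abs(row_sums - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "states", tuple(self.states))

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None


@dataclass(frozen=True)
class MarkovModel:
    """State space, transitions and cycle length (years)."""

    transitions: TransitionMatrix
    cycle_length: float = 1.0
    absorbing: tuple = ("death",)

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle length must be positive")
        for state in self.absorbing:
            i = self.transitions.state_index(state)
            row = self.transitions.probabilities[i]
            expected = np.zeros(len(self.states))
            expected[i] = 1.0
            if np.abs(row - expected).max() > _ROW_TOL:
                raise ValueError(f"absorbing state {state!r} must have an identity row")

    @property
    def states(self) -> tuple:
        return self.transitions.states


def counts_to_probabilities(
    counts: TransitionCounts, absorbing: Sequence[str] = ("death",)
) -> TransitionMatrix:
    """Row-normalized maximum-likelihood transition probabilities.

    Absorbing states with no observed outflow get identity rows; any other
    zero-count row is rejected as unidentifiable.
    """
    probs = np.zeros_like(counts.counts)
    absorbing_set = set(absorbing)
    for i, state in enumerate(counts.states):
        total = counts.counts[i].sum()
        if total == 0:
            if state in absorbing_set:
                probs[i, i] = 1.0
                continue
            raise ValueError(f"state {state!r} has no observed transitions")
        probs[i] = counts.counts[i] / total
    return TransitionMatrix(counts.states, probs)


def run_cohort(model: MarkovModel, initial: Sequence[float], n_cycles: int) -> np.ndarray:
    """Propagate occupancy; returns a (n_cycles + 1, n_states) trace.

    ``trace[0]`` is the initial vector and ``trace[t+1] = trace[t] @ P``.
    Total occupancy is conserved because rows of P sum to one.
    """
    init = np.asarray(initial, dtype=float)
    if init.shape != (len(model.states),):
        raise ValueError("initial occupancy length must match the state list")
    if (init < 0).any():
        raise ValueError("occupancy must be non-negative")
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    trace = np.empty((n_cycles + 1, len(model.states)))
    trace[0] = init
    for t in range(n_cycles):
        trace[t + 1] = trace[t] @ model.transitions.probabilities
    return trace


def care_home_person_years(trace: np.ndarray, model: MarkovModel, care_state: str = "care_home") -> float:
    """Person-years spent in the care state over the simulated cycles.

    Occupancy at the start of each of the ``n`` cycles (trace rows 0..n-1)
    is accrued for one cycle length — the cycle-start accrual convention.
    """
    idx = model.transitions.state_index(care_state)
    return float(trace[:-1, idx].sum() * model.cycle_length)


def stroke_ltc_cost(person_years: float, unit_cost: Money) -> Money:
    """Cost of post-stroke institutional care: person-years × unit cost."""
    if person_years < 0:
        raise ValueError("person-years must be non-negative")
    return unit_cost * person_years


def vad_ltc_cost(dementia_social_care_cost: Money, vad_share: float = 0.17) -> Money:
    """Vascular-dementia LTC cost as a share of total dementia social care.

    The default 17% is the proportion of all dementia attributed to
    vascular dementia.
    """
    if not 0.0 <= vad_share <= 1.0:
        raise ValueError("vad_share must lie in [0, 1]")
    return dementia_social_care_cost * vad_share


def sample_transition_matrix(
    counts: TransitionCounts,
    rng: Union[int, np.random.Generator, None] = None,
    absorbing: Sequence[str] = ("death",),
) -> TransitionMatrix:
    """Draw one transition matrix from row-wise Dirichlet(counts) posteriors."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    probs = np.zeros_like(counts.counts)
    absorbing_set = set(absorbing)
    for i, state in enumerate(counts.states):
        row = counts.counts[i]
        if row.sum() == 0:
            if state in absorbing_set:
                probs[i, i] = 1.0
                continue
            raise ValueError(f"state {state!r} has no observed transitions")
        # Dirichlet needs strictly positive concentrations; structural zeros
        # (never-observed destinations) stay exactly zero.
        support = row > 0
        if support.sum() == 1:
            probs[i, support] = 1.0
        else:
            probs[i, support] = gen.dirichlet(row[support])
    return TransitionMatrix(counts.states, probs)


def psa_stroke_ltc(
    counts: TransitionCounts,
    initial: Sequence[float],
    n_cycles: int,
    unit_cost: Money,
    care_state: str = "care_home",
    cycle_length: float = 1.0,
    absorbing: Sequence[str] = ("death",),
    n_trials: int = 1000,
    seed: Optional[int] = None,
) -> PSAResult:
    """PSA over the stroke LTC cost: Dirichlet transition draws per trial."""
    if n_trials < 2:
        raise ValueError("PSA requires at least 2 trials")
    rng = np.random.default_rng(seed)
    trials = np.empty(n_trials)
    for k in range(n_trials):
        matrix = sample_transition_matrix(counts, rng, absorbing)
        model = MarkovModel(matrix, cycle_length=cycle_length, absorbing=tuple(absorbing))
        trace = run_cohort(model, initial, n_cycles)
        py = care_home_person_years(trace, model, care_state)
        trials[k] = float(stroke_ltc_cost(py, unit_cost).amount)
    return summarize_trials(trials, seed=seed)
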