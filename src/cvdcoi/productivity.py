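"""Human-capital production losses from premature CVD mortality and morbidity.

Mortality losses value each death as the discounted stream of expected
earnings from the age at death to retirement at 65: for each remaining
working year, the age/sex-specific employment rate times the annual wage,
discounted at 3.5% per annum. Earnings in the year of death are counted
undiscounted; discounting starts the following year. Morbidity losses
combine sickness-absence days valued at the average daily wage with
ESA/DLA benefit payments (claimants × weekly amount × weeks the claim is
in payment during the year). DLA dementia claims are scaled by the
vascular-dementia share before costing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .money import Money, _to_decimal
from .sensitivity import PSAResult, summarize_trials

__all__ = [
    "DeathRecord",
    "LaborMarketTable",
    "BenefitClaim",
    "SicknessRecord",
    "present_value_earnings",
    "mortality_loss",
    "sickness_loss",
    "benefit_cost",
    "adjust_dementia_claims",
    "psa_mortality",
]

WORKING_AGE_START = 15
RETIREMENT_AGE = 65


@dataclass(frozen=True)
class DeathRecord:
    """CVD deaths in one age band × sex cell."""

    age_low: int
    age_high: int  # exclusive
    sex: str
    deaths: float
    nation: str = ""
    year: str = ""

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise ValueError("death counts must be non-negative")
        if self.age_high <= self.age_low:
            raise ValueError("age band must be non-empty")

    @property
    def midpoint(self) -> int:
        return (self.age_low + self.age_high) // 2


class LaborMarketTable:
    """Employment rate and annual wage per (age band, sex)."""

    def __init__(
        self,
        bands: Iterable[tuple],
        price_year: int = 2022,
    ):
        """``bands``: iterables of (sex, age_low, age_high, employment_rate, annual_wage)."""
        self.price_year = price_year
        self._bands: dict[str, list[tuple]] = {}
        for sex, lo, hi, rate, wage in bands:
            if not 0.0 <= rate <= 1.0:
                raise ValueError("employment rates must lie in [0, 1]")
            if wage < 0:
                raise ValueError("wages must be non-negative")
            self._bands.setdefault(sex, []).append((int(lo), int(hi), float(rate), float(wage)))
        for rows in self._bands.values():
            rows.sort()

    def lookup(self, age: int, sex: str) -> tuple[float, float]:
        for lo, hi, rate, wage in self._bands.get(sex, ()):
            if lo <= age < hi:
                return rate, wage
        raise KeyError(f"no labour-market band covering age {age} for sex {sex!r}")

    def scaled(self, wage_factor: float = 1.0, rate_factor: float = 1.0) -> "LaborMarketTable":
        """Copy with wages and employment rates scaled (rates clipped to [0, 1])."""
        rows = [
            (sex, lo, hi, min(max(rate * rate_factor, 0.0), 1.0), max(wage * wage_factor, 0.0))
            for sex, bands in self._bands.items()
            for lo, hi, rate, wage in bands
        ]
        return LaborMarketTable(rows, price_year=self.price_year)


def present_value_earnings(
    age_at_death: int,
    sex: str,
    table: LaborMarketTable,
    rate: float = 0.035,
    retirement: int = RETIREMENT_AGE,
    working_age_start: int = WORKING_AGE_START,
) -> Money:
    """Discounted expected earnings from death to retirement.

    Sums employment_rate(y) × wage(y) × (1+rate)^-(y-age) over whole years
    y from max(age, working start) to retirement − 1. Zero at or past
    retirement. The year of death itself is undiscounted.
    """
    if age_at_death < 0:
        raise ValueError("age at death must be non-negative")
    total = 0.0
    for year_age in range(max(age_at_death, working_age_start), retirement):
        emp, wage = table.lookup(year_age, sex)
        total += emp * wage * (1.0 + rate) ** (-(year_age - age_at_death))
    return Money(_to_decimal(total), table.price_year)


def mortality_loss(
    deaths: Iterable[DeathRecord],
    table: LaborMarketTable,
    rate: float = 0.035,
) -> Money:
    """Σ deaths × present value of earnings at the band midpoint."""
    total = Money.zero(table.price_year)
    for record in deaths:
        if record.midpoint >= RETIREMENT_AGE:
            continue
        pv = present_value_earnings(record.midpoint, record.sex, table, rate=rate)
        total = total + pv * _to_decimal(record.deaths)
    return total


@dataclass(frozen=True)
class SicknessRecord:
    """Sickness-absence days attributed to CVD, and the daily wage."""

    days: float
    daily_wage: Money

    def __post_init__(self) -> None:
        if self.days < 0 or self.daily_wage.amount < 0:
            raise ValueError("sickness record values must be non-negative")


def sickness_loss(record: SicknessRecord) -> Money:
    """Days of sickness absence × average daily wage."""
    return record.daily_wage * _to_decimal(record.days)


@dataclass(frozen=True)
class BenefitClaim:
    """A quarter's benefit claims (ESA or DLA) for a CVD-related condition."""

    scheme: str
    claimants: float
    weekly_amount: Money
    weeks_remaining_in_year: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.scheme not in {"ESA", "DLA"}:
            raise ValueError("scheme must be ESA or DLA")
        if self.claimants < 0:
            raise ValueError("claimant counts must be non-negative")
        if not 0 <= self.weeks_remaining_in_year <= 52:
            raise ValueError("weeks remaining must lie in [0, 52]")


def benefit_cost(claims: Iterable[BenefitClaim], *, price_year: Optional[int] = None) -> Money:
    """Σ claimants × weekly amount × weeks the claim pays out this year.

    An empty claim list sums to zero; pass ``price_year`` so the zero has
    a price basis to attach to.
    """
    total: Optional[Money] = None
    for claim in claims:
        term = claim.weekly_amount * (
            _to_decimal(claim.claimants) * _to_decimal(claim.weeks_remaining_in_year)
        )
        total = term if total is None else total + term
    if total is None:
        if price_year is None:
            raise ValueError("empty claim list: pass price_year for the zero total")
        return Money.zero(price_year)
    return total


def adjust_dementia_claims(claim: BenefitClaim, vad_share: float = 0.17) -> BenefitClaim:
    """Scale a DLA dementia claim to its vascular-dementia share."""
    if not 0.0 <= vad_share <= 1.0:
        raise ValueError("vad_share must lie in [0, 1]")
    return BenefitClaim(
        scheme=claim.scheme,
        claimants=claim.claimants * vad_share,
        weekly_amount=claim.weekly_amount,
        weeks_remaining_in_year=claim.weeks_remaining_in_year,
        condition=claim.condition,
    )


def psa_mortality(
    deaths: Sequence[DeathRecord],
    table: LaborMarketTable,
    wage_rel_sd: float = 0.05,
    employment_rel_sd: float = 0.02,
    rate: float = 0.035,
    n: int = 1000,
    seed: Optional[int] = None,
) -> PSAResult:
    """PSA over the mortality loss: wages and employment rates perturbed.

    Each trial scales all wages by a Normal(1, wage_rel_sd) factor and all
    employment rates by Normal(1, employment_rel_sd) (rates clipped to
    [0, 1]), then recomputes the loss. Zero SDs give degenerate trials
    equal to the base case.
    """
    if n < 2:
        raise ValueError("PSA requires at least 2 trials")
    if wage_rel_sd < 0 or employment_rel_sd < 0:
        raise ValueError("relative SDs must be non-negative")
    rng = np.random.default_rng(seed)
    trials = np.empty(n)
    for k in range(n):
        wf = float(rng.normal(1.0, wage_rel_sd)) if wage_rel_sd else 1.0
        ef = float(rng.normal(1.0, employment_rel_sd)) if employment_rel_sd else 1.0
        wf = max(wf, 0.0)
        perturbed = table.scaled(wage_factor=wf, rate_factor=ef)
        trials[k] = float(mortality_loss(deaths, perturbed, rate=rate).amount)
    return summarize_trials(trials, seed=seed)
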