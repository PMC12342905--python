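"""Top-down apportionment of aggregate NHS spending and activity to CVD.

The share constants (generalist case-mix, stroke/TIA-to-neurology ratio,
vascular-to-general-surgery ratio, primary-care hypertension proxy,
vascular-dementia share) live in a versioned YAML registry rather than in
code, because the analysis itself varies them in sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .money import Money, _to_decimal

__all__ = [
    "ApportionmentRule",
    "RuleRegistry",
    "ActivityRecord",
    "SecondaryBudget",
    "apply_share",
    "activity_cost",
    "uncoded_attribution",
    "wales_inpatient_residual",
    "wales_outpatient_share",
    "scale_by_population",
    "load_default_rules",
    "read_activity_csv",
]


@dataclass(frozen=True)
class ApportionmentRule:
    """A named attribution share with its citation."""

    name: str
    share: float
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.share <= 1.0:
            raise ValueError(f"share for {self.name!r} must lie in [0, 1], got {self.share}")


class RuleRegistry:
    """Named collection of apportionment rules loaded from YAML."""

    def __init__(self, rules: Iterable[ApportionmentRule]):
        self._rules = {rule.name: rule for rule in rules}

    def __getitem__(self, name: str) -> ApportionmentRule:
        try:
            return self._rules[name]
        except KeyError:
            raise KeyError(f"no apportionment rule named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._rules

    def names(self) -> list[str]:
        return sorted(self._rules)

    def share(self, name: str) -> float:
        return self[name].share

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RuleRegistry":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "RuleRegistry":
        rules = [
            ApportionmentRule(name=name, share=float(spec["share"]), source=spec.get("source", ""))
            for name, spec in raw.items()
        ]
        return cls(rules)


def load_default_rules() -> RuleRegistry:
    """The packaged registry of attribution shares."""
    text = resources.files("cvdcoi.data").joinpath("apportionment_rules.yaml").read_text()
    return RuleRegistry._from_mapping(yaml.safe_load(text))


@dataclass(frozen=True)
class ActivityRecord:
    """One specialty's activity volume and unit cost.

    ``dedicated`` marks specialties whose whole activity is CVD (e.g.
    cardiology); generalist specialties are attributed the case-mix share.
    """

    specialty: str
    activity: float
    unit_cost: Money
    dedicated: bool = True

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError(f"activity for {self.specialty!r} must be non-negative")
        if self.unit_cost.amount < 0:
            raise ValueError(f"unit cost for {self.specialty!r} must be non-negative")


@dataclass(frozen=True)
class SecondaryBudget:
    """A nation's gross circulatory-disease secondary-care budget."""

    total: Money

    def __post_init__(self) -> None:
        if self.total.amount < 0:
            raise ValueError("secondary-care budget must be non-negative")


def apply_share(amount: Money, rule: ApportionmentRule) -> Money:
    """Attribute ``amount`` × share to CVD."""
    return amount * Decimal(str(rule.share))


def activity_cost(
    records: Iterable[ActivityRecord], cvd_share: float, *, price_year: Optional[int] = None
) -> Money:
    """Σ activity × unit cost, with the generalist share applied where due.

    Dedicated-CVD specialties contribute in full; generalist records are
    scaled by ``cvd_share``. An empty record list sums to zero; pass
    ``price_year`` so the zero has a price basis to attach to.
    """
    if not 0.0 <= cvd_share <= 1.0:
        raise ValueError("cvd_share must lie in [0, 1]")
    total: Optional[Money] = None
    for record in records:
        share = Decimal(1) if record.dedicated else Decimal(str(cvd_share))
        term = record.unit_cost * (_to_decimal(record.activity) * share)
        total = term if total is None else total + term
    if total is None:
        if price_year is None:
            raise ValueError("empty record list: pass price_year for the zero total")
        return Money.zero(price_year)
    return total


def uncoded_attribution(coded_cvd: float, coded_total: float, uncoded: float) -> float:
    """Allocate uncoded activity by the coded CVD proportion.

    Fractional attributed counts are kept fractional; rounding only happens
    at costing/report time.
    """
    if coded_total <= 0:
        raise ValueError("coded_total must be positive")
    if coded_cvd < 0 or coded_cvd > coded_total:
        raise ValueError("coded_cvd must lie in [0, coded_total]")
    if uncoded < 0:
        raise ValueError("uncoded count must be non-negative")
    return uncoded * coded_cvd / coded_total


def wales_inpatient_residual(budget: SecondaryBudget, ae_est: Money, op_est: Money) -> Money:
    """Welsh inpatient cost as budget minus the A&E and outpatient estimates.

    Wales publishes only the gross circulatory-disease secondary-care
    budget; the A&E and outpatient products are backed out and the
    remainder is inpatient care. A negative remainder signals inconsistent
    inputs and is rejected.
    """
    residual = budget.total - ae_est - op_est
    if residual.amount < 0:
        raise ValueError("negative inpatient residual: A&E + outpatient estimates exceed the budget")
    return residual


def wales_outpatient_share(
    england_outpatient_cvd: Money,
    england_secondary_cvd_total: Money,
    welsh_budget: SecondaryBudget,
) -> Money:
    """Scale the Welsh budget by England's outpatient share of secondary care."""
    if england_secondary_cvd_total.amount <= 0:
        raise ValueError("England secondary-care total must be positive")
    ratio = england_outpatient_cvd.amount / england_secondary_cvd_total.amount
    return welsh_budget.total * ratio


def scale_by_population(england_cost: Money, nation_pop: float, england_pop: float) -> Money:
    """Project an England-only cost onto another nation by population."""
    if england_pop <= 0:
        raise ValueError("England population must be positive")
    if nation_pop < 0:
        raise ValueError("nation population must be non-negative")
    return england_cost * (_to_decimal(nation_pop) / _to_decimal(england_pop))


def read_activity_csv(path: Union[str, Path], price_year: int) -> list[ActivityRecord]:
    """Read the activity interface CSV.

    Columns: nation, fiscal_year, specialty, activity, unit_cost_gbp,
    class (``dedicated`` or ``generalist``).
    """
    frame = pd.read_csv(path, dtype={"unit_cost_gbp": str})
    records = []
    for row in frame.itertuples(index=False):
        cls = str(row.__getattribute__("class")).strip().lower()
        if cls not in {"dedicated", "generalist"}:
            raise ValueError(f"unknown specialty class {cls!r}")
        records.append(
            ActivityRecord(
                specialty=str(row.specialty),
                activity=float(row.activity),
                unit_cost=Money(_to_decimal(str(row.unit_cost_gbp)), price_year),
                dedicated=(cls == "dedicated"),
            )
        )
    return records
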