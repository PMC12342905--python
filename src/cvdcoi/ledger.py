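"""Cost ledger: the backbone container every costing stage writes into.

A :class:`CostLedger` holds at most one entry per (component, nation,
fiscal year), all expressed in a single price year. Aggregation is exact
decimal summation; inflation and currency conversion move amounts between
price bases using GDP-deflator and exchange-rate tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

from .money import (
    HOME_NATIONS,
    CostComponent,
    FiscalYear,
    Money,
    Nation,
    PriceYearMismatchError,
    _to_decimal,
)

__all__ = [
    "CostEntry",
    "CostLedger",
    "DeflatorTable",
    "ExchangeRateTable",
    "aggregate",
    "inflate",
    "convert_currency",
]

LEDGER_COLUMNS = ["component", "nation", "fiscal_year", "amount_gbp", "price_year", "provenance"]


@dataclass(frozen=True)
class CostEntry:
    component: CostComponent
    nation: Nation
    year: FiscalYear
    value: Money
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.value.amount < 0:
            raise ValueError("cost entries must be non-negative")

    @property
    def key(self) -> tuple:
        return (self.component, self.nation, self.year.start_year)


class CostLedger:
    """Collection of cost entries sharing one price year.

    ``allow_aggregate_nation`` opens the ledger for UK-tagged rows; it is
    only meant for historical comparison tables published as UK aggregates
    without a nation split.
    """

    def __init__(self, entries: Iterable[CostEntry] = (), *, allow_aggregate_nation: bool = False):
        self._entries: dict[tuple, CostEntry] = {}
        self.allow_aggregate_nation = allow_aggregate_nation
        for entry in entries:
            self.add(entry)

    def add(self, entry: CostEntry) -> None:
        if entry.nation is Nation.UK and not self.allow_aggregate_nation:
            raise ValueError("UK totals are derived by aggregation, not stored")
        if entry.key in self._entries:
            raise ValueError(f"duplicate ledger entry for {entry.key}")
        if self._entries:
            first = next(iter(self._entries.values()))
            if entry.value.price_year != first.value.price_year:
                raise PriceYearMismatchError(
                    "all ledger entries must share one price year "
                    f"({first.value.price_year} != {entry.value.price_year})"
                )
        self._entries[entry.key] = entry

    def __iter__(self) -> Iterator[CostEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def price_year(self) -> Optional[int]:
        if not self._entries:
            return None
        return next(iter(self._entries.values())).value.price_year

    def get(self, component: CostComponent, nation: Nation, year: FiscalYear) -> Optional[CostEntry]:
        return self._entries.get((component, nation, year.start_year))

    def aggregate(
        self,
        components: Optional[Iterable[CostComponent]] = None,
        nations: Optional[Iterable[Nation]] = None,
        year: Optional[FiscalYear] = None,
        *,
        price_year: Optional[int] = None,
    ) -> Money:
        """Exact sum of the matching entries; an empty match is zero.

        ``price_year`` only matters for the zero returned on an empty
        ledger/match; populated ledgers use their own price year.
        """
        comp_set = None if components is None else set(components)
        nat_set = None if nations is None else set(nations)
        total = Decimal(0)
        base_year = self.price_year if self.price_year is not None else price_year
        if base_year is None:
            raise ValueError("cannot infer price year for an empty ledger; pass price_year")
        for entry in self._entries.values():
            if comp_set is not None and entry.component not in comp_set:
                continue
            if nat_set is not None and entry.nation not in nat_set:
                continue
            if year is not None and entry.year != year:
                continue
            total += entry.value.amount
        return Money(total, base_year)

    # -- CSV interface ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "component": e.component.value,
                "nation": e.nation.value,
                "fiscal_year": e.year.label,
                "amount_gbp": str(e.value.amount),
                "price_year": e.value.price_year,
                "provenance": e.provenance,
            }
            for e in self._entries.values()
        ]
        return pd.DataFrame(rows, columns=LEDGER_COLUMNS)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, allow_aggregate_nation: bool = False) -> "CostLedger":
        missing = set(LEDGER_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"ledger table missing columns: {sorted(missing)}")
        ledger = cls(allow_aggregate_nation=allow_aggregate_nation)
        for row in frame.itertuples(index=False):
            ledger.add(
                CostEntry(
                    component=CostComponent(row.component),
                    nation=Nation(row.nation),
                    year=FiscalYear.parse(str(row.fiscal_year)),
                    value=Money(_to_decimal(str(row.amount_gbp)), int(row.price_year)),
                    provenance=str(row.provenance) if not pd.isna(row.provenance) else "",
                )
            )
        return ledger

    @classmethod
    def from_csv(cls, path: Union[str, Path], *, allow_aggregate_nation: bool = False) -> "CostLedger":
        frame = pd.read_csv(path, dtype={"amount_gbp": str})
        return cls.from_frame(frame, allow_aggregate_nation=allow_aggregate_nation)


def aggregate(
    ledger: CostLedger,
    components: Optional[Iterable[CostComponent]] = None,
    nations: Optional[Iterable[Nation]] = None,
    year: Optional[FiscalYear] = None,
    *,
    price_year: Optional[int] = None,
) -> Money:
    """Functional form of :meth:`CostLedger.aggregate`."""
    return ledger.aggregate(components, nations, year, price_year=price_year)


class DeflatorTable:
    """GDP-deflator index by calendar year, used to restate real terms."""

    def __init__(self, indices: Mapping[int, Numeric]):
        self._indices: dict[int, Decimal] = {}
        for year, idx in indices.items():
            d = _to_decimal(idx)
            if d <= 0:
                raise ValueError(f"deflator index for {year} must be positive")
            self._indices[int(year)] = d

    def index(self, year: int) -> Decimal:
        try:
            return self._indices[year]
        except KeyError:
            raise KeyError(f"no deflator index for year {year}") from None

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DeflatorTable":
        frame = pd.read_csv(path, dtype={1: str})
        year_col, idx_col = frame.columns[:2]
        return cls({int(r[year_col]): str(r[idx_col]) for _, r in frame.iterrows()})


Numeric = Union[int, float, str, Decimal]


def inflate(amount: Money, to_year: int, table: DeflatorTable) -> Money:
    """Restate ``amount`` into ``to_year`` prices by the deflator ratio."""
    ratio = table.index(to_year) / table.index(amount.price_year)
    return Money(amount.amount * ratio, to_year)


class ExchangeRateTable:
    """GBP per foreign-currency-unit rates by (currency, fiscal year)."""

    def __init__(self, rates: Mapping[tuple[str, str], Numeric]):
        self._rates: dict[tuple[str, str], Decimal] = {}
        for (currency, year_label), rate in rates.items():
            d = _to_decimal(rate)
            if d <= 0:
                raise ValueError(f"exchange rate for {currency} {year_label} must be positive")
            self._rates[(currency.upper(), year_label)] = d

    def rate(self, currency: str, year: FiscalYear) -> Decimal:
        key = (currency.upper(), year.label)
        try:
            return self._rates[key]
        except KeyError:
            raise KeyError(f"no exchange rate for {currency} in {year.label}") from None

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ExchangeRateTable":
        frame = pd.read_csv(path, dtype=str)
        cur_col, year_col, rate_col = frame.columns[:3]
        return cls(
            {(r[cur_col], r[year_col]): r[rate_col] for _, r in frame.iterrows()}
        )


def convert_currency(
    amount: Numeric,
    table: ExchangeRateTable,
    currency: str,
    year: FiscalYear,
    *,
    price_year: Optional[int] = None,
) -> Money:
    """Convert a foreign-currency amount to GBP at the fiscal year's rate."""
    rate = table.rate(currency, year)
    py = price_year if price_year is not None else year.start_year
    return Money(_to_decimal(amount) * rate, py)
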