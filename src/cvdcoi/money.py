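"""Exact-decimal money, fiscal years, nations and cost components.

Money amounts are carried as :class:`decimal.Decimal` at full precision and
tagged with the calendar *price year* their purchasing power refers to.
Arithmetic between amounts expressed in different price years is a hard
error — real-terms series must be deflated onto a common base before they
can be added. Rounding to pennies or to billions happens only at report
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Union

Numeric = Union[int, float, str, Decimal]

__all__ = [
    "Money",
    "FiscalYear",
    "Nation",
    "CostComponent",
    "DIRECT_COMPONENTS",
    "INDIRECT_COMPONENTS",
    "HOME_NATIONS",
    "PriceYearMismatchError",
    "discount_factor",
    "percent_change",
    "round_half_up",
]


class PriceYearMismatchError(ValueError):
    """Arithmetic attempted between amounts in different price years."""


def _to_decimal(value: Numeric) -> Decimal:
    if isinstance(value, Decimal):
        d = value
    elif isinstance(value, int):
        d = Decimal(value)
    elif isinstance(value, float):
        # repr round-trips the float exactly enough for money bookkeeping
        d = Decimal(repr(value))
    elif isinstance(value, str):
        d = Decimal(value)
    else:
        raise TypeError(f"cannot interpret {type(value).__name__} as a money amount")
    if not d.is_finite():
        raise ValueError("money amounts must be finite")
    return d


def round_half_up(value: Numeric, places: int = 1) -> Decimal:
    """Round a number half-up to ``places`` decimal places (report style)."""
    q = Decimal(1).scaleb(-places)
    return _to_decimal(value).quantize(q, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class Money:
    """A GBP amount expressed in real terms of ``price_year``."""

    amount: Decimal
    price_year: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "amount", _to_decimal(self.amount))

    @classmethod
    def zero(cls, price_year: int) -> "Money":
        return cls(Decimal(0), price_year)

    def _check_compatible(self, other: "Money") -> None:
        if not isinstance(other, Money):
            raise TypeError("expected a Money operand")
        if other.price_year != self.price_year:
            raise PriceYearMismatchError(
                f"cannot combine amounts in {self.price_year} and "
                f"{other.price_year} prices; deflate to a common base first"
            )

    def __add__(self, other: "Money") -> "Money":
        self._check_compatible(other)
        return Money(self.amount + other.amount, self.price_year)

    def __sub__(self, other: "Money") -> "Money":
        self._check_compatible(other)
        return Money(self.amount - other.amount, self.price_year)

    def __neg__(self) -> "Money":
        return Money(-self.amount, self.price_year)

    def __mul__(self, factor: Numeric) -> "Money":
        return Money(self.amount * _to_decimal(factor), self.price_year)

    __rmul__ = __mul__

    def scaled(self, factor: Numeric) -> "Money":
        return self * factor

    def rounded(self) -> "Money":
        """Quantized to the penny, half-up."""
        return Money(self.amount.quantize(Decimal("0.01"), ROUND_HALF_UP), self.price_year)

    def in_billions(self, places: int = 3) -> Decimal:
        return round_half_up(self.amount / Decimal(10) ** 9, places)

    def __float__(self) -> float:
        return float(self.amount)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"£{self.amount:,.2f} ({self.price_year} prices)"


@dataclass(frozen=True, order=True)
class FiscalYear:
    """A UK fiscal year such as 2021/22, identified by its starting year."""

    start_year: int
    label: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if not self.label:
            object.__setattr__(self, "label", f"{self.start_year}/{(self.start_year + 1) % 100:02d}")
        else:
            parsed = self.parse(self.label)
            if parsed.start_year != self.start_year:
                raise ValueError(f"label {self.label!r} does not match start year {self.start_year}")

    @classmethod
    def parse(cls, label: str) -> "FiscalYear":
        """Parse labels like ``2021/22`` or ``2019/2020`` into a fiscal year."""
        try:
            first, second = label.split("/")
            start = int(first)
            end = int(second)
        except ValueError as exc:
            raise ValueError(f"not a fiscal-year label: {label!r}") from exc
        if end < 100:
            end += (start // 100) * 100
            if end < start:  # century wrap, e.g. 1999/00
                end += 100
        if end != start + 1:
            raise ValueError(f"fiscal-year label {label!r} does not span consecutive years")
        return cls(start)


class Nation(str, Enum):
    """The four UK nations plus the UK aggregate.

    The UK aggregate is a derived quantity: ledgers reject UK-tagged raw
    entries unless explicitly opened for historical comparison tables.
    """

    ENGLAND = "England"
    SCOTLAND = "Scotland"
    WALES = "Wales"
    NORTHERN_IRELAND = "NorthernIreland"
    UK = "UK"


HOME_NATIONS = frozenset(
    {Nation.ENGLAND, Nation.SCOTLAND, Nation.WALES, Nation.NORTHERN_IRELAND}
)


class CostComponent(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    A_AND_E = "a_and_e"
    PRIMARY_CARE = "primary_care"
    MEDICATIONS = "medications"
    DEVICES = "devices"
    LTC_STROKE = "ltc_stroke"
    LTC_VAD = "ltc_vad"
    MORBIDITY = "morbidity"
    MORTALITY = "mortality"
    INFORMAL_CARE = "informal_care"


DIRECT_COMPONENTS = frozenset(
    {
        CostComponent.INPATIENT,
        CostComponent.OUTPATIENT,
        CostComponent.A_AND_E,
        CostComponent.PRIMARY_CARE,
        CostComponent.MEDICATIONS,
        CostComponent.DEVICES,
        CostComponent.LTC_STROKE,
        CostComponent.LTC_VAD,
    }
)
INDIRECT_COMPONENTS = frozenset(
    {CostComponent.MORBIDITY, CostComponent.MORTALITY, CostComponent.INFORMAL_CARE}
)


def discount_factor(years_ahead: int, rate: float = 0.035) -> float:
    """Present-value factor ``(1 + rate) ** -years_ahead``.

    The default 3.5% per annum is the HM Treasury recommended rate for
    discounting future costs.
    """
    if years_ahead < 0:
        raise ValueError("years_ahead must be non-negative")
    if rate <= -1:
        raise ValueError("rate must exceed -1")
    return (1.0 + rate) ** (-years_ahead)


def percent_change(old: Money, new: Money) -> float:
    """Signed percentage change from ``old`` to ``new`` (same price year)."""
    old._check_compatible(new)
    if old.amount <= 0:
        raise ValueError("percent change needs a positive baseline")
    return float((new.amount - old.amount) / old.amount * 100)
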