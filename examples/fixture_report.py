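"""Reassemble the published UK CVD cost tables and print the headline figures.

Loads the packaged per-nation cost ledger, derives the UK totals by exact
decimal aggregation and prints the headline cost of illness plus the
changes against the 2015 baseline.
"""

from decimal import Decimal

from cvdcoi.money import (
    CostComponent,
    FiscalYear,
    HOME_NATIONS,
    Nation,
    percent_change,
    round_half_up,
)
from cvdcoi.reporting import RunConfig, run_pipeline
from cvdcoi.synthetic import load_fixtures

report = run_pipeline(RunConfig(mode="fixtures", fiscal_year="2021/22"))
print("Headline cost of CVD in the UK, 2021/22 (2022 prices, GBP bn):")
for name, value in report.headline.items():
    print(f"  {name:>9}: {value}")

fx = load_fixtures()
y = FiscalYear.parse("2021/22")
old = fx.ehn2015.get(CostComponent.INPATIENT, Nation.UK, FiscalYear(2015)).value
new = fx.direct.aggregate({CostComponent.INPATIENT}, HOME_NATIONS, y)
print(f"\nInpatient care grew {round_half_up(percent_change(old, new), 1)}% since the 2015 baseline")

added = fx.direct.aggregate(
    {CostComponent.DEVICES, CostComponent.LTC_STROKE, CostComponent.LTC_VAD}, HOME_NATIONS, y
)
print(f"Long-term care + devices (newly costed components) add £{added.in_billions()} bn")

share = fx.direct.aggregate(None, HOME_NATIONS, y).amount / Decimal(
    fx.constants["uk_public_health_spending"]["2021/22"]
)
print(f"Direct costs are {round_half_up(share * 100, 1)}% of UK public health spending")
# The headline total combines direct care costs with productivity and
# informal-care losses; the deltas show what changed since 2015 and what
# the newly added cost components contribute.
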