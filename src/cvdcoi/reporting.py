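"""Pipeline orchestration and report rendering.

``run_pipeline`` executes either the fixture pass-through (the published
cost tables re-assembled and re-totalled from the packaged ledger) or a
fully synthetic end-to-end run in which every modelled component —
informal care, post-stroke long-term care, vascular dementia, mortality
and morbidity losses, and the top-down direct components — is recomputed
from generated inputs. Reports are component × nation tables with derived
UK totals, closing to the penny, plus headline figures in £bn to 3 dp
(half-up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import apportionment as app
from . import informal as inf
from . import markov as mk
from . import productivity as prod
from .ledger import CostEntry, CostLedger
from .money import (
    DIRECT_COMPONENTS,
    HOME_NATIONS,
    INDIRECT_COMPONENTS,
    CostComponent,
    FiscalYear,
    Money,
    Nation,
    _to_decimal,
)
from .sensitivity import PSAResult, TornadoEntry
from .synthetic import (
    LaborDeathsConfig,
    SurveyGeneratorConfig,
    gen_labor_and_deaths,
    gen_stroke_counts,
    gen_survey,
    load_fixtures,
)

__all__ = ["RunConfig", "CostReport", "run_pipeline", "render_tornado", "render_psa_box"]

_NATION_ORDER = [Nation.ENGLAND, Nation.SCOTLAND, Nation.WALES, Nation.NORTHERN_IRELAND]

#: Synthetic study-population constants: total and over-50 populations and
#: per-nation scale factors used by the synthetic pipeline. Chosen once to
#: be demographically plausible for the four nations.
_SYNTH = {
    "population": {
        Nation.ENGLAND: 56_500_000,
        Nation.SCOTLAND: 5_480_000,
        Nation.WALES: 3_170_000,
        Nation.NORTHERN_IRELAND: 1_900_000,
    },
    "population_over_50": {
        Nation.ENGLAND: 21_400_000,
        Nation.SCOTLAND: 2_100_000,
        Nation.WALES: 1_300_000,
        Nation.NORTHERN_IRELAND: 700_000,
    },
    "stroke_discharges": {
        Nation.ENGLAND: 85_000,
        Nation.SCOTLAND: 9_000,
        Nation.WALES: 5_000,
        Nation.NORTHERN_IRELAND: 2_500,
    },
    "dementia_social_care": {  # modelled total dementia social-care cost, GBP
        Nation.ENGLAND: 11_200_000_000,
        Nation.SCOTLAND: 880_000_000,
        Nation.WALES: 640_000_000,
        Nation.NORTHERN_IRELAND: 280_000_000,
    },
    "general_medicine_budget": {  # gross admissions spend routed via case-mix share
        Nation.ENGLAND: 9_000_000_000,
        Nation.SCOTLAND: 950_000_000,
        Nation.WALES: 620_000_000,
        Nation.NORTHERN_IRELAND: 300_000_000,
    },
    "dedicated_cvd_inpatient": {
        Nation.ENGLAND: 3_900_000_000,
        Nation.SCOTLAND: 420_000_000,
        Nation.WALES: 260_000_000,
        Nation.NORTHERN_IRELAND: 120_000_000,
    },
    "primary_care_budget": {
        Nation.ENGLAND: 10_500_000_000,
        Nation.SCOTLAND: 930_000_000,
        Nation.WALES: 1_180_000_000,
        Nation.NORTHERN_IRELAND: 340_000_000,
    },
    "medications": {
        Nation.ENGLAND: 1_600_000_000,
        Nation.SCOTLAND: 160_000_000,
        Nation.WALES: 98_000_000,
        Nation.NORTHERN_IRELAND: 68_000_000,
    },
    "england_device_spend": 340_000_000,
    "stroke_ltc_unit_cost": 40_000,  # GBP per person-year in institutional care
    "sickness_days": {
        Nation.ENGLAND: 7_500_000,
        Nation.SCOTLAND: 900_000,
        Nation.WALES: 650_000,
        Nation.NORTHERN_IRELAND: 420_000,
    },
    "daily_wage": 120,
    "under65_cvd_deaths": {
        Nation.ENGLAND: 20_000,
        Nation.SCOTLAND: 2_700,
        Nation.WALES: 1_400,
        Nation.NORTHERN_IRELAND: 650,
    },
    "minimum_wage": 9.50,
    "average_wage": 15.50,
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "fixtures"  # "fixtures" or "synthetic"
    fiscal_year: str = "2021/22"
    seed: int = 0
    include_components: Optional[frozenset] = None  # None = all
    survey: SurveyGeneratorConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mode not in {"fixtures", "synthetic"}:
            raise ValueError("mode must be 'fixtures' or 'synthetic'")
        FiscalYear.parse(self.fiscal_year)


@dataclass(frozen=True)
class CostReport:
    """Component × nation cost tables with derived UK totals and headlines."""

    fiscal_year: str
    price_year: int
    direct: pd.DataFrame
    indirect: pd.DataFrame
    totals: Mapping[str, Money]
    headline: Mapping[str, Decimal]

    def to_dict(self) -> dict:
        def table(frame: pd.DataFrame) -> dict:
            return {
                component: {nation: str(frame.at[component, nation]) for nation in frame.columns}
                for component in frame.index
            }

        return {
            "fiscal_year": self.fiscal_year,
            "price_year": self.price_year,
            "direct": table(self.direct),
            "indirect": table(self.indirect),
            "totals": {k: str(v.amount) for k, v in self.totals.items()},
            "headline_bn": {k: str(v) for k, v in self.headline.items()},
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _report_from_ledger(ledger: CostLedger, fiscal_year: str, components: Iterable[CostComponent]) -> CostReport:
    year = FiscalYear.parse(fiscal_year)
    price_year = ledger.price_year or 2022
    comp_set = set(components)

    def table(comps: Sequence[CostComponent]) -> pd.DataFrame:
        rows = {}
        for comp in comps:
            row = {}
            uk = Money.zero(price_year)
            for nation in _NATION_ORDER:
                entry = ledger.get(comp, nation, year)
                value = entry.value if entry else Money.zero(price_year)
                row[nation.value] = value.amount
                uk = uk + value
            row["UK"] = uk.amount
            rows[comp.value] = row
        return pd.DataFrame.from_dict(rows, orient="index")

    direct_comps = [c for c in CostComponent if c in DIRECT_COMPONENTS and c in comp_set]
    indirect_comps = [c for c in CostComponent if c in INDIRECT_COMPONENTS and c in comp_set]
    direct = table(direct_comps)
    indirect = table(indirect_comps)
    direct_total = Money(sum((Decimal(direct.at[c.value, "UK"]) for c in direct_comps), Decimal(0)), price_year)
    indirect_total = Money(sum((Decimal(indirect.at[c.value, "UK"]) for c in indirect_comps), Decimal(0)), price_year)
    grand = direct_total + indirect_total
    totals = {"direct": direct_total, "indirect": indirect_total, "total": grand}
    headline = {k: v.in_billions(3) for k, v in totals.items()}
    return CostReport(
        fiscal_year=fiscal_year,
        price_year=price_year,
        direct=direct,
        indirect=indirect,
        totals=totals,
        headline=headline,
    )


def _synthetic_ledger(config: RunConfig) -> CostLedger:
    """Run every modelled component on generated inputs; assemble a ledger."""
    year = FiscalYear.parse(config.fiscal_year)
    price_year = 2022
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    ledger = CostLedger()
    rules = app.load_default_rules()
    s = _SYNTH

    def add(component: CostComponent, nation: Nation, value: Money, provenance: str) -> None:
        ledger.add(CostEntry(component, nation, year, value, provenance))

    eng_pop = s["population"][Nation.ENGLAND]

    # --- direct components via top-down apportionment -------------------
    gm_share = rules["general_medicine_cvd"]
    pc_share = rules["primary_care_cvd"]
    for nation in _NATION_ORDER:
        gm = Money(s["general_medicine_budget"][nation], price_year)
        dedicated = Money(s["dedicated_cvd_inpatient"][nation], price_year)
        add(CostComponent.INPATIENT, nation, dedicated + app.apply_share(gm, gm_share),
            "dedicated CVD HRGs + case-mix share of general medicine")
        records = [
            app.ActivityRecord("cardiology", 90_000 * s["population"][nation] / eng_pop, Money(160, price_year), True),
            app.ActivityRecord("general_medicine", 300_000 * s["population"][nation] / eng_pop, Money(140, price_year), False),
        ]
        add(CostComponent.OUTPATIENT, nation, app.activity_cost(records, gm_share.share),
            "activity x unit cost, generalist share applied")
        coded_cvd, coded_total = 52_000, 1_000_000
        attended = 1_200_000 * s["population"][nation] / eng_pop
        uncoded = 0.08 * attended
        cvd_visits = attended * (1 - 0.08) * coded_cvd / coded_total + app.uncoded_attribution(
            coded_cvd, coded_total, uncoded
        )
        add(CostComponent.A_AND_E, nation, Money(180, price_year) * _to_decimal(cvd_visits),
            "coded share + uncoded attribution, x weighted unit cost")
        add(CostComponent.PRIMARY_CARE, nation,
            app.apply_share(Money(s["primary_care_budget"][nation], price_year), pc_share),
            "hypertension-proxy share of primary-care budget")
        add(CostComponent.MEDICATIONS, nation, Money(s["medications"][nation], price_year),
            "prescription cost analysis, cardiovascular chapter")
        add(CostComponent.DEVICES, nation,
            app.scale_by_population(Money(s["england_device_spend"], price_year),
                                    s["population"][nation], eng_pop),
            "England device spend scaled by population")

    # --- long-term care: Markov stroke model + VaD share -----------------
    true_matrix = mk.TransitionMatrix(
        mk.DEFAULT_STATES,
        np.array(
            [
                [0.80, 0.08, 0.04, 0.08],
                [0.30, 0.45, 0.15, 0.10],
                [0.00, 0.00, 0.75, 0.25],
                [0.00, 0.00, 0.00, 1.00],
            ]
        ),
    )
    counts = gen_stroke_counts(2_000, true_matrix, seed=seeds[0])
    matrix = mk.counts_to_probabilities(counts)
    model = mk.MarkovModel(matrix)
    vad_rule = rules["vad_share_of_dementia"]
    for nation in _NATION_ORDER:
        n0 = s["stroke_discharges"][nation]
        initial = [0.70 * n0, 0.24 * n0, 0.06 * n0, 0.0]
        trace = mk.run_cohort(model, initial, n_cycles=10)
        py = mk.care_home_person_years(trace, model)
        add(CostComponent.LTC_STROKE, nation,
            mk.stroke_ltc_cost(py, Money(s["stroke_ltc_unit_cost"], price_year)),
            "Markov cohort person-years x unit cost")
        add(CostComponent.LTC_VAD, nation,
            mk.vad_ltc_cost(Money(s["dementia_social_care"][nation], price_year), vad_rule.share),
            "VaD share of dementia social-care cost")

    # --- indirect: mortality, morbidity, informal care -------------------
    deaths_cfg = LaborDeathsConfig(age_high=65)
    _, labor = gen_labor_and_deaths(deaths_cfg, seed=seeds[1])
    for nation in _NATION_ORDER:
        cfg = LaborDeathsConfig(total_deaths=s["under65_cvd_deaths"][nation], age_high=65)
        nation_deaths, _ = gen_labor_and_deaths(cfg, seed=seeds[1])
        add(CostComponent.MORTALITY, nation, prod.mortality_loss(nation_deaths, labor),
            "human-capital present value of earnings to 65")
        sick = prod.SicknessRecord(s["sickness_days"][nation], Money(s["daily_wage"], price_year))
        claims = [
            prod.BenefitClaim("ESA", 20_000 * s["population"][nation] / eng_pop, Money(115, price_year), 40),
            prod.adjust_dementia_claims(
                prod.BenefitClaim("DLA", 30_000 * s["population"][nation] / eng_pop,
                                  Money(95, price_year), 45, condition="dementia"),
                vad_rule.share,
            ),
        ]
        add(CostComponent.MORBIDITY, nation, prod.sickness_loss(sick) + prod.benefit_cost(claims),
            "sickness days x daily wage + ESA/DLA claims")

    survey_cfg = config.survey or SurveyGeneratorConfig(seed=int(seeds[2].generate_state(1)[0] % 2**31))
    frame, _ = gen_survey(survey_cfg)
    disability = inf.fit_binary_margin(frame, "severely_disabled")
    in_help = inf.fit_binary_margin(frame, "in_household_help", covariates=inf.ORDERED_COVARIATES)
    out_help = inf.fit_binary_margin(frame, "out_household_help", covariates=inf.ORDERED_COVARIATES)
    carer_margins: dict[int, dict[str, inf.MarginalEffect]] = {}
    hours: dict[int, float] = {}
    wages: dict[int, Money] = {}
    policy = inf.WagePolicy(
        minimum_wage={config.fiscal_year: s["minimum_wage"]},
        average_wage={config.fiscal_year: s["average_wage"]},
    )
    for slot in (1, 2, 3):
        margins = inf.fit_ordered_margins(frame, f"carer{slot}_freq")
        carer_margins[slot] = {f: m for f, m in margins.items() if f != "none"}
        observed = frame[frame[f"carer{slot}_freq"] != "none"]
        hours[slot] = float(observed[f"carer{slot}_hours"].mean())
        slot_wages = [
            inf.carer_wage(
                inf.CarerRecord(
                    frequency=row[f"carer{slot}_freq"],
                    hours_per_contact=row[f"carer{slot}_hours"],
                    relationship=row[f"carer{slot}_relationship"],
                    employed=bool(row[f"carer{slot}_employed"]),
                ),
                row["age"],
                policy,
                config.fiscal_year,
            ).amount
            for _, row in observed.head(2_000).iterrows()
        ]
        wages[slot] = Money(sum(slot_wages) / len(slot_wages), price_year)
    prevalence = float(frame["has_cvd"].mean())
    for nation in _NATION_ORDER:
        inputs = inf.InformalCareInputs(
            population_over_50=s["population_over_50"][nation],
            cvd_prevalence=prevalence,
            disability=disability,
            in_help=in_help,
            out_help=out_help,
            carer_margins=carer_margins,
            hours_per_contact=hours,
            hourly_wage=wages,
            price_year=price_year,
        )
        add(CostComponent.INFORMAL_CARE, nation, inf.informal_care_cost(inputs),
            "survey marginal effects x hours x imputed wage")
    return ledger


def run_pipeline(config: RunConfig) -> CostReport:
    """Execute the configured pipeline and assemble the cost report."""
    components = (
        set(CostComponent)
        if config.include_components is None
        else set(config.include_components)
    )
    if config.mode == "fixtures":
        ledger = load_fixtures().direct
        merged = CostLedger()
        for entry in ledger:
            merged.add(entry)
        for entry in load_fixtures().indirect:
            merged.add(entry)
        ledger = merged
    else:
        ledger = _synthetic_ledger(config)
    return _report_from_ledger(ledger, config.fiscal_year, components)


def render_tornado(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Tornado rows sorted by swing, ready for CSV export / plotting."""
    if not entries:
        raise ValueError("no tornado entries to render")
    frame = pd.DataFrame(
        [
            {
                "name": e.name,
                "pct_change_low": e.pct_change_low,
                "pct_change_high": e.pct_change_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    )
    return frame.sort_values("swing", ascending=False, ignore_index=True)


def render_psa_box(results: Mapping[str, PSAResult]) -> pd.DataFrame:
    """Five-number summaries per model/nation for box-plot rendering."""
    if not results:
        raise ValueError("no PSA results to render")
    return pd.DataFrame(
        [
            {
                "name": name,
                "minimum": r.minimum,
                "q25": r.q25,
                "median": r.median,
                "q75": r.q75,
                "maximum": r.maximum,
                "n": r.n,
            }
            for name, r in results.items()
        ]
    )
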