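"""Top-down attribution rules: shares, residuals and population scaling."""

from decimal import Decimal

import pytest

from cvdcoi.apportionment import (
    ActivityRecord,
    ApportionmentRule,
    SecondaryBudget,
    activity_cost,
    apply_share,
    load_default_rules,
    scale_by_population,
    uncoded_attribution,
    wales_inpatient_residual,
    wales_outpatient_share,
)
from cvdcoi.money import CostComponent, FiscalYear, HOME_NATIONS, Money, Nation

GM = ApportionmentRule("general_medicine_cvd", 0.179)


class TestRules:
    def test_share_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ApportionmentRule("bad", 1.2)

    def test_packaged_registry_constants(self):
        rules = load_default_rules()
        assert rules.share("general_medicine_cvd") == 0.179
        assert rules.share("stroke_tia_to_neurology") == 0.30
        assert rules.share("vascular_to_general_surgery") == 0.072
        assert rules.share("primary_care_cvd") == 0.12
        assert rules.share("vad_share_of_dementia") == 0.17


class TestApplyShare:
    @pytest.mark.parametrize(
        "amount,share,expected",
        [(1000, 0.179, "179.000"), (1234, 0.0, "0"), (1234, 1.0, "1234")],
    )
    def test_share_arithmetic(self, amount, share, expected):
        rule = ApportionmentRule("r", share)
        assert apply_share(Money(amount, 2022), rule).amount == Decimal(expected)

    def test_linear_in_amount(self):
        a = apply_share(Money(100, 2022), GM)
        b = apply_share(Money(300, 2022), GM)
        assert b.amount == 3 * a.amount


class TestActivityCost:
    def test_dedicated_specialty_full_cost(self):
        records = [ActivityRecord("cardiology", 10, Money(50, 2022), dedicated=True)]
        assert activity_cost(records, 1.0).amount == Decimal(500)

    def test_generalist_share_applied(self):
        records = [ActivityRecord("general_medicine", 100, Money(50, 2022), dedicated=False)]
        assert activity_cost(records, 0.179).amount == Decimal("895.000")

    def test_empty_list_is_zero(self):
        assert activity_cost([], 0.5, price_year=2022).amount == 0

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            ActivityRecord("x", -1, Money(50, 2022))


class TestUncodedAttribution:
    @pytest.mark.parametrize(
        "cvd,total,uncoded,expected",
        [(20, 100, 50, 10.0), (0, 100, 50, 0.0), (100, 100, 7, 7.0)],
    )
    def test_proportional_allocation(self, cvd, total, uncoded, expected):
        assert uncoded_attribution(cvd, total, uncoded) == pytest.approx(expected)

    def test_zero_coded_total_rejected(self):
        with pytest.raises(ValueError):
            uncoded_attribution(0, 0, 10)

    @pytest.mark.parametrize("cvd", [0, 1, 49, 99, 100])
    def test_never_exceeds_uncoded(self, cvd):
        assert uncoded_attribution(cvd, 100, 37) <= 37


class TestWalesResidual:
    def test_subtraction(self):
        budget = SecondaryBudget(Money(100, 2022))
        out = wales_inpatient_residual(budget, Money(10, 2022), Money(20, 2022))
        assert out.amount == Decimal(70)

    def test_boundary_zero(self):
        budget = SecondaryBudget(Money(30, 2022))
        assert wales_inpatient_residual(budget, Money(10, 2022), Money(20, 2022)).amount == 0

    def test_negative_residual_rejected(self):
        budget = SecondaryBudget(Money(100, 2022))
        with pytest.raises(ValueError, match="residual"):
            wales_inpatient_residual(budget, Money(60, 2022), Money(50, 2022))

    def test_components_recompose_to_budget(self):
        budget = SecondaryBudget(Money("507001280.51", 2022))
        ae, op = Money("9583101.19", 2022), Money("66795502.00", 2022)
        residual = wales_inpatient_residual(budget, ae, op)
        assert (residual + ae + op).amount == budget.total.amount


class TestWalesOutpatientShare:
    def test_ratio_scaling(self):
        out = wales_outpatient_share(
            Money(10, 2022), Money(100, 2022), SecondaryBudget(Money(430_000_000, 2022))
        )
        assert out.amount == Decimal(43_000_000)

    def test_zero_numerator(self):
        out = wales_outpatient_share(
            Money(0, 2022), Money(100, 2022), SecondaryBudget(Money(430, 2022))
        )
        assert out.amount == 0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            wales_outpatient_share(Money(10, 2022), Money(0, 2022), SecondaryBudget(Money(1, 2022)))

    @pytest.mark.parametrize("year", ["2019/20", "2020/21", "2021/22"])
    def test_fixture_welsh_split_internally_consistent(self, fixtures, year):
        """England's outpatient share of secondary care, applied to the Welsh
        circulatory budget, reproduces the Welsh outpatient row within 1%."""
        fy = FiscalYear.parse(year)

        def cell(component, nation):
            return fixtures.direct.get(component, nation, fy).value

        eng_secondary = (
            cell(CostComponent.INPATIENT, Nation.ENGLAND)
            + cell(CostComponent.OUTPATIENT, Nation.ENGLAND)
            + cell(CostComponent.A_AND_E, Nation.ENGLAND)
        )
        welsh_budget = SecondaryBudget(
            cell(CostComponent.INPATIENT, Nation.WALES)
            + cell(CostComponent.OUTPATIENT, Nation.WALES)
            + cell(CostComponent.A_AND_E, Nation.WALES)
        )
        implied = wales_outpatient_share(
            cell(CostComponent.OUTPATIENT, Nation.ENGLAND), eng_secondary, welsh_budget
        )
        actual = cell(CostComponent.OUTPATIENT, Nation.WALES)
        assert abs(implied.amount - actual.amount) <= actual.amount * Decimal("0.01")


class TestPopulationScaling:
    def test_identity_ratio(self):
        assert scale_by_population(Money(100, 2022), 5, 5).amount == Decimal(100)

    def test_zero_population(self):
        assert scale_by_population(Money(100, 2022), 0, 5).amount == 0

    def test_zero_england_population_rejected(self):
        with pytest.raises(ValueError):
            scale_by_population(Money(100, 2022), 1, 0)

    def test_fixture_device_rows_share_one_population_ratio(self, fixtures):
        """Scotland/England device spend ratio is constant across all three
        years (the same census population ratio was applied), ~0.09706."""
        ratios = []
        for year in ("2019/20", "2020/21", "2021/22"):
            fy = FiscalYear.parse(year)
            eng = fixtures.direct.get(CostComponent.DEVICES, Nation.ENGLAND, fy).value.amount
            sco = fixtures.direct.get(CostComponent.DEVICES, Nation.SCOTLAND, fy).value.amount
            ratios.append(sco / eng)
        assert max(ratios) - min(ratios) <= Decimal("1e-4") * ratios[0]
        assert float(ratios[0]) == pytest.approx(0.09706, abs=5e-5)
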