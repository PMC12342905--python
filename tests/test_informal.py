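"""Informal-care model: marginal effects, wage imputation, cost formula, PSA."""

import numpy as np
import pandas as pd
import pytest

from cvdcoi.informal import (
    ANNUALIZATION,
    CarerRecord,
    InformalCareInputs,
    MarginalEffect,
    WagePolicy,
    carer_wage,
    combined_help_margin,
    fit_binary_margin,
    fit_ordered_margins,
    informal_care_cost,
    margin_ci,
    psa_informal,
)
from cvdcoi.money import Money
from cvdcoi.synthetic import SurveyGeneratorConfig, gen_survey


def exact(margin):
    return MarginalEffect(margin, 0.0, margin, margin)


def make_inputs(**overrides):
    base = dict(
        population_over_50=1000.0,
        cvd_prevalence=0.5,
        disability=exact(1.0),
        in_help=exact(1.0),
        out_help=exact(1.0),
        carer_margins={1: {"daily": exact(1.0)}},
        hours_per_contact={1: 1.0},
        hourly_wage={1: Money(10, 2022)},
    )
    base.update(overrides)
    return InformalCareInputs(**base)


class TestMarginCi:
    def test_reported_upper_bound_matches_published_row(self):
        low, high = margin_ci(0.1448, 0.003754)
        assert high == pytest.approx(0.1522, abs=1e-9)

    def test_daily_first_carer_row(self):
        assert margin_ci(0.1233, 0.004540) == (0.1144, 0.1322)

    def test_zero_se_degenerate(self):
        assert margin_ci(0.3, 0.0) == (0.3, 0.3)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            margin_ci(0.3, -0.1)


class TestBinaryMargin:
    def test_recovers_generator_truth_within_ci(self, survey_default):
        frame, truth = survey_default
        eff = fit_binary_margin(frame, "severely_disabled")
        assert eff.ci_low <= truth["ame"]["severely_disabled"] <= eff.ci_high

    def test_null_effect_within_three_se(self):
        cfg = SurveyGeneratorConfig(
            n=20_000,
            seed=9,
            disability=SurveyGeneratorConfig().disability.__class__(-2.2, 0.0, 0.4, -0.2, 0.35),
        )
        frame, truth = gen_survey(cfg)
        assert truth["ame"]["severely_disabled"] == 0.0
        eff = fit_binary_margin(frame, "severely_disabled")
        assert abs(eff.margin) <= 3 * eff.se

    def test_single_class_outcome_rejected(self, survey_default):
        frame = survey_default[0].copy()
        frame["severely_disabled"] = 1
        with pytest.raises(ValueError, match="single-class"):
            fit_binary_margin(frame, "severely_disabled")

    def test_discrete_change_routes_agree(self, survey_default):
        """The analytic AME equals both the subgroup-prediction contrast and
        the statsmodels margeff dummy computation (independent route)."""
        import statsmodels.api as sm

        frame, _ = survey_default
        eff = fit_binary_margin(frame, "severely_disabled")

        X = sm.add_constant(
            np.column_stack(
                [frame[c].to_numpy(float) for c in ("age", "gender", "n_comorbidities", "has_cvd")]
            )
        )
        res = sm.Logit(frame["severely_disabled"].to_numpy(float), X).fit(disp=0)
        X1, X0 = X.copy(), X.copy()
        X1[:, -1], X0[:, -1] = 1.0, 0.0
        contrast = np.mean(res.predict(X1) - res.predict(X0))
        assert eff.margin == pytest.approx(contrast, abs=1e-10)

        margeff = res.get_margeff(at="overall", method="dydx", dummy=True)
        assert eff.margin == pytest.approx(margeff.margeff[-1], rel=1e-6)
        assert eff.se == pytest.approx(margeff.margeff_se[-1], rel=1e-4)


class TestOrderedMargins:
    def test_recovers_generator_truth(self, survey_default):
        frame, truth = survey_default
        margins = fit_ordered_margins(frame, "carer1_freq")
        for category, eff in margins.items():
            true_ame = truth["ordered_ame"][1][category]
            assert abs(eff.margin - true_ame) <= max(4 * eff.se, 0.01)

    def test_category_ames_sum_to_zero(self, survey_default):
        margins = fit_ordered_margins(survey_default[0], "carer1_freq")
        assert sum(e.margin for e in margins.values()) == pytest.approx(0.0, abs=1e-8)

    def test_null_effect_recovered(self):
        slots = SurveyGeneratorConfig().carer_slots
        null_slot = slots[0].__class__(0.0, 0.3, 0.15, -0.1, slots[0].cutpoints)
        cfg = SurveyGeneratorConfig(n=20_000, seed=17, carer_slots=(null_slot,) + slots[1:])
        frame, truth = gen_survey(cfg)
        margins = fit_ordered_margins(frame, "carer1_freq")
        for category, eff in margins.items():
            assert truth["ordered_ame"][1][category] == 0.0
            assert abs(eff.margin) <= 4 * eff.se

    def test_single_category_rejected(self, survey_default):
        frame = survey_default[0].copy()
        frame["carer1_freq"] = "daily"
        with pytest.raises(ValueError, match="fewer than two"):
            fit_ordered_margins(frame, "carer1_freq")

    def test_unknown_category_rejected(self, survey_default):
        frame = survey_default[0].head(500).copy()
        frame.loc[frame.index[0], "carer1_freq"] = "fortnightly"
        with pytest.raises(ValueError, match="unknown"):
            fit_ordered_margins(frame, "carer1_freq")


class TestCarerWage:
    policy = WagePolicy(minimum_wage={"2021/22": 9.50}, average_wage={"2021/22": 15.50})

    def test_spouse_of_over_65_gets_minimum_wage(self):
        carer = CarerRecord("daily", 2.0, relationship="spouse", employed=True)
        wage = carer_wage(carer, 70, self.policy, "2021/22")
        assert float(wage.amount) == 9.50

    def test_employed_neighbour_of_60_year_old_gets_average_wage(self):
        carer = CarerRecord("weekly", 2.0, relationship="neighbour", employed=True)
        wage = carer_wage(carer, 60, self.policy, "2021/22")
        assert float(wage.amount) == 15.50

    def test_unemployed_carer_gets_minimum_wage_any_age(self):
        carer = CarerRecord("weekly", 2.0, relationship="child", employed=False)
        assert float(carer_wage(carer, 55, self.policy, "2021/22").amount) == 9.50

    def test_missing_year_rejected(self):
        carer = CarerRecord("daily", 2.0, employed=False)
        with pytest.raises(KeyError):
            carer_wage(carer, 70, self.policy, "1999/00")


class TestInformalCareCost:
    def test_zero_prevalence_zero_cost(self):
        assert float(informal_care_cost(make_inputs(cvd_prevalence=0.0)).amount) == 0.0

    def test_product_identity_daily_carer(self):
        # 1000 people x 0.5 prevalence x 365 contacts x 1 h x £10
        cost = informal_care_cost(make_inputs())
        assert float(cost.amount) == pytest.approx(1_825_000.0)

    def test_monotone_in_margins_wages_hours(self):
        base = float(informal_care_cost(make_inputs(disability=exact(0.5))).amount)
        higher_margin = float(informal_care_cost(make_inputs(disability=exact(0.6))).amount)
        higher_wage = float(
            informal_care_cost(
                make_inputs(disability=exact(0.5), hourly_wage={1: Money(12, 2022)})
            ).amount
        )
        higher_hours = float(
            informal_care_cost(
                make_inputs(disability=exact(0.5), hours_per_contact={1: 1.5})
            ).amount
        )
        assert higher_margin > base and higher_wage > base and higher_hours > base

    def test_proportion_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_inputs(cvd_prevalence=1.2)

    def test_term_log_composes_exactly(self):
        log: list = []
        cost = informal_care_cost(make_inputs(), term_log=log)
        assert log[-1]["total"] == pytest.approx(float(cost.amount))

    def test_help_margins_combine_additively_capped(self):
        assert combined_help_margin(0.1124, 0.2427) == pytest.approx(0.3551)
        assert combined_help_margin(0.7, 0.6) == 1.0


def _brute_force_per_capita(cfg, frame_size=40_000, seed=101):
    """Respondent-level expected attributable cost under the true models."""
    from cvdcoi.informal import FREQUENCY_ORDER
    from cvdcoi.synthetic import Covariates, _sigmoid

    frame, truth = gen_survey(
        SurveyGeneratorConfig(
            n=frame_size, seed=seed, cvd_prevalence=cfg.cvd_prevalence,
            disability=cfg.disability, in_help=cfg.in_help, out_help=cfg.out_help,
            carer_slots=cfg.carer_slots,
        )
    )
    cov = Covariates(
        age=frame["age"].to_numpy(float),
        gender=frame["gender"].to_numpy(float),
        comorbidities=frame["n_comorbidities"].to_numpy(float),
        household_size=frame["household_size"].to_numpy(float),
    )
    n = len(frame)
    ones, zeros = np.ones(n), np.zeros(n)

    def delta(coeffs):
        return _sigmoid(coeffs.linear_predictor(cov, ones)) - _sigmoid(
            coeffs.linear_predictor(cov, zeros)
        )

    d_dis = delta(cfg.disability)
    d_help = np.minimum(delta(cfg.in_help) + delta(cfg.out_help), 1.0)
    hours, wage = 2.0, 12.0
    per_person = np.zeros(n)
    agg_sum = 0.0
    for slot_coeffs in cfg.carer_slots:
        p1 = slot_coeffs.category_probs(cov, ones)
        p0 = slot_coeffs.category_probs(cov, zeros)
        for k, cat in enumerate(FREQUENCY_ORDER):
            if cat == "none":
                continue
            dm = p1[:, k] - p0[:, k]
            per_person += dm * ANNUALIZATION[cat] * hours * wage
            agg_sum += dm.mean() * ANNUALIZATION[cat] * hours * wage
    brute = float(np.mean(d_dis * d_help * per_person))
    aggregate = float(
        np.mean(d_dis) * min(delta(cfg.in_help).mean() + delta(cfg.out_help).mean(), 1.0) * agg_sum
    )
    return brute, aggregate


class TestAggregationOracle:
    def test_homogeneous_effects_agree_within_one_percent(self):
        """With covariate effects switched off the discrete changes are the
        same for every respondent, so the aggregate product formula must
        match the respondent-level expectation almost exactly."""
        L = SurveyGeneratorConfig().disability.__class__
        O = SurveyGeneratorConfig().carer_slots[0].__class__
        cfg = SurveyGeneratorConfig(
            disability=L(-1.5, 0.9, 0.0, 0.0, 0.0),
            in_help=L(-2.0, 0.85, 0.0, 0.0, 0.0),
            out_help=L(-1.2, 1.15, 0.0, 0.0, 0.0),
            carer_slots=(
                O(0.8, 0.0, 0.0, 0.0, (0.9, 1.7, 2.5, 3.5)),
                O(0.8, 0.0, 0.0, 0.0, (1.7, 2.4, 3.1, 4.0)),
                O(0.8, 0.0, 0.0, 0.0, (2.4, 3.0, 3.6, 4.4)),
            ),
        )
        brute, aggregate = _brute_force_per_capita(cfg)
        assert brute == pytest.approx(aggregate, rel=0.01)

    def test_default_config_discrepancy_measured_and_bounded(self):
        """Under realistic heterogeneous effects the product of sample-mean
        margins understates the respondent-level expectation because the
        per-respondent effects are positively correlated; the gap is
        measured here and stays bounded."""
        brute, aggregate = _brute_force_per_capita(SurveyGeneratorConfig())
        rel = abs(brute - aggregate) / aggregate
        assert rel < 0.25


class TestInformalPsa:
    def test_zero_ses_degenerate_trials(self):
        result = psa_informal(make_inputs(), n_trials=50, seed=1)
        base = float(informal_care_cost(make_inputs()).amount)
        assert all(t == pytest.approx(base) for t in result.trials)

    def test_seed_reproducibility(self):
        inputs = make_inputs(disability=MarginalEffect(0.5, 0.05, 0.4, 0.6))
        a = psa_informal(inputs, n_trials=100, seed=3)
        b = psa_informal(inputs, n_trials=100, seed=3)
        assert a.trials == b.trials

    def test_summary_ordering(self):
        inputs = make_inputs(disability=MarginalEffect(0.5, 0.05, 0.4, 0.6))
        r = psa_informal(inputs, n_trials=200, seed=4)
        assert r.minimum <= r.q25 <= r.median <= r.q75 <= r.maximum

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            psa_informal(make_inputs(), n_trials=1, seed=0)
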