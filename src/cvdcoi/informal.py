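"""Informal-care cost model driven by survey marginal effects.

The economic burden of unpaid care is built multiplicatively from survey
microdata on over-50s: the population over 50, the prevalence of CVD
(heart attack, hypertension or stroke), the average marginal effect (AME)
of CVD on severe disability and on receiving help, the AMEs of CVD on
each carer slot's contact frequency, the hours of care per contact, and
an imputed hourly wage for the carer (national minimum wage for carers
assumed out of work, average wage otherwise).

AMEs come from logistic (binary outcomes) and ordered-logistic (contact
frequency) regressions. The AME of the CVD flag is the discrete change:
the sample mean of the difference in predicted probability with the flag
switched on versus off, all other covariates at observed values. Standard
errors are delta-method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .money import Money, _to_decimal
from .sensitivity import PSAResult, summarize_trials

__all__ = [
    "FREQUENCIES",
    "FREQUENCY_ORDER",
    "ANNUALIZATION",
    "CarerRecord",
    "SurveyRespondent",
    "MarginalEffect",
    "WagePolicy",
    "InformalCareInputs",
    "margin_ci",
    "fit_binary_margin",
    "fit_ordered_margins",
    "carer_wage",
    "combined_help_margin",
    "informal_care_cost",
    "psa_informal",
    "respondents_to_frame",
]

logger = logging.getLogger(__name__)

#: Carer contact-frequency categories, most to least frequent.
FREQUENCIES = ("daily", "weekly", "monthly", "annually")

#: Ordered-outcome category order (least to most intense) including no carer.
FREQUENCY_ORDER = ("none", "annually", "monthly", "weekly", "daily")

#: Contacts per year for each frequency category.
ANNUALIZATION = {"daily": 365, "weekly": 52, "monthly": 12, "annually": 1}

#: Relationships assumed retired alongside a respondent over 65.
RETIRED_WITH_RESPONDENT = frozenset({"sibling", "spouse", "friend", "parent"})

BINARY_COVARIATES = ("age", "gender", "n_comorbidities")
ORDERED_COVARIATES = ("age", "gender", "n_comorbidities", "household_size")


@dataclass(frozen=True)
class CarerRecord:
    frequency: str
    hours_per_contact: float
    relationship: str = ""
    employed: bool = True

    def __post_init__(self) -> None:
        if self.frequency not in FREQUENCIES:
            raise ValueError(f"unknown contact frequency {self.frequency!r}")
        if self.hours_per_contact < 0:
            raise ValueError("hours per contact must be non-negative")


@dataclass(frozen=True)
class SurveyRespondent:
    """One survey record: over-50 respondent with up to three carers."""

    age: float
    gender: int
    n_comorbidities: int
    household_size: int
    has_cvd: bool
    severely_disabled: bool
    in_household_help: bool
    out_household_help: bool
    carers: tuple = ()

    def __post_init__(self) -> None:
        if self.age <= 50:
            raise ValueError("respondents are over 50")
        if len(self.carers) > 3:
            raise ValueError("at most three carer slots")


def respondents_to_frame(respondents: Iterable[SurveyRespondent]) -> pd.DataFrame:
    """Flatten respondents into the survey CSV layout (carer slots as columns)."""
    rows = []
    for r in respondents:
        row = {
            "age": r.age,
            "gender": r.gender,
            "n_comorbidities": r.n_comorbidities,
            "household_size": r.household_size,
            "has_cvd": int(r.has_cvd),
            "severely_disabled": int(r.severely_disabled),
            "in_household_help": int(r.in_household_help),
            "out_household_help": int(r.out_household_help),
        }
        for k in range(3):
            carer = r.carers[k] if k < len(r.carers) else None
            row[f"carer{k + 1}_freq"] = carer.frequency if carer else ""
            row[f"carer{k + 1}_hours"] = carer.hours_per_contact if carer else np.nan
            row[f"carer{k + 1}_relationship"] = carer.relationship if carer else ""
            row[f"carer{k + 1}_employed"] = int(carer.employed) if carer else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MarginalEffect:
    """Point estimate, delta-method SE and 95% CI for a regression margin."""

    margin: float
    se: float
    ci_low: float
    ci_high: float
    pseudo_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if not self.ci_low <= self.margin <= self.ci_high:
            raise ValueError("margin must lie inside its confidence interval")


def margin_ci(margin: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal CI ``margin ± z·se`` rounded to 4 dp for reporting.

    z is fixed at 1.96 for the conventional 95% level.
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    z = 1.96 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf(0.5 + level / 2))
    low = float(round(margin - z * se, 4))
    high = float(round(margin + z * se, 4))
    return low, high


def _effect(margin: float, se: float, pseudo_r2: Optional[float] = None) -> MarginalEffect:
    low, high = margin_ci(margin, se)
    # reported CI is rounded to 4 dp; widen marginally so the unrounded
    # margin always lies inside
    low = min(low, margin)
    high = max(high, margin)
    return MarginalEffect(margin=margin, se=se, ci_low=low, ci_high=high, pseudo_r2=pseudo_r2)


def _design(data: pd.DataFrame, covariates: Sequence[str], exposure: str) -> np.ndarray:
    cols = [data[c].to_numpy(dtype=float) for c in covariates]
    cols.append(data[exposure].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_binary_margin(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = BINARY_COVARIATES,
    exposure: str = "has_cvd",
) -> MarginalEffect:
    """AME of the CVD flag on a binary outcome from a logistic regression.

    The AME is the discrete change averaged over the sample; its SE is
    delta-method with the analytic gradient.
    """
    y = data[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"outcome {outcome!r} is single-class (all {classes[0]:g}); a logistic fit is undefined"
        )
    n_params = len(covariates) + 2  # + intercept + exposure
    if len(data) < 10 * (n_params - 1):
        raise ValueError("need at least 10 observations per covariate")
    X = sm.add_constant(_design(data, covariates, exposure))
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic fit for {outcome!r} failed: {exc}") from exc
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 50:
        raise ValueError(f"logistic fit for {outcome!r} shows separation-like divergence")

    beta = res.params
    exog1 = X.copy()
    exog0 = X.copy()
    exog1[:, -1] = 1.0
    exog0[:, -1] = 0.0
    p1 = 1.0 / (1.0 + np.exp(-exog1 @ beta))
    p0 = 1.0 / (1.0 + np.exp(-exog0 @ beta))
    ame = float(np.mean(p1 - p0))
    grad = np.mean(
        (p1 * (1 - p1))[:, None] * exog1 - (p0 * (1 - p0))[:, None] * exog0, axis=0
    )
    se = float(np.sqrt(grad @ res.cov_params() @ grad))
    return _effect(ame, se, pseudo_r2=float(res.prsquared))


def fit_ordered_margins(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ORDERED_COVARIATES,
    exposure: str = "has_cvd",
    categories: Sequence[str] = FREQUENCY_ORDER,
) -> dict[str, MarginalEffect]:
    """Per-category AMEs of the CVD flag from an ordered logistic regression.

    Returns an AME for every category in ``categories`` (including the
    lowest, e.g. having no carer); across the full category set the AMEs
    sum to zero because probabilities sum to one at any covariate value.
    """
    values = data[outcome].astype(str)
    unknown = set(values.unique()) - set(categories)
    if unknown:
        raise ValueError(f"unknown outcome categories {sorted(unknown)}; expected {list(categories)}")
    observed = [c for c in categories if (values == c).any()]
    if len(observed) < 2:
        raise ValueError(f"outcome {outcome!r} has fewer than two observed categories")
    cat = pd.Categorical(values, categories=list(categories), ordered=True)
    # drop never-observed categories: thresholds for them are unidentified
    cat = cat.remove_unused_categories()
    used = list(cat.categories)
    y = pd.Series(cat, index=data.index, name=outcome)
    X = _design(data, covariates, exposure)
    model = OrderedModel(y, X, distr="logit")
    try:
        res = model.fit(method="bfgs", disp=0, maxiter=500)
    except Exception as exc:
        raise ValueError(f"ordered logistic fit for {outcome!r} failed: {exc}") from exc
    if not np.isfinite(res.params).all():
        raise ValueError(f"ordered logistic fit for {outcome!r} did not converge")

    exog1 = X.copy()
    exog0 = X.copy()
    exog1[:, -1] = 1.0
    exog0[:, -1] = 0.0

    def category_ames(params: np.ndarray) -> np.ndarray:
        p1 = model.predict(params, exog=exog1, which="prob")
        p0 = model.predict(params, exog=exog0, which="prob")
        return np.mean(p1 - p0, axis=0)

    params = np.asarray(res.params, dtype=float)
    ames = category_ames(params)
    # delta-method SE via central-difference Jacobian over the parameters
    cov = np.asarray(res.cov_params())
    jac = np.empty((len(used), len(params)))
    for j in range(len(params)):
        step = 1e-6 * max(1.0, abs(params[j]))
        hi = params.copy()
        lo = params.copy()
        hi[j] += step
        lo[j] -= step
        jac[:, j] = (category_ames(hi) - category_ames(lo)) / (2 * step)
    ses = np.sqrt(np.einsum("ij,jk,ik->i", jac, cov, jac))
    pseudo = float(res.prsquared) if hasattr(res, "prsquared") else None
    return {
        cat: _effect(float(ames[i]), float(ses[i]), pseudo_r2=pseudo)
        for i, cat in enumerate(used)
    }


@dataclass(frozen=True)
class WagePolicy:
    """Hourly wages per fiscal-year label, GBP, plus the retirement age."""

    minimum_wage: Mapping[str, float]
    average_wage: Mapping[str, float]
    retirement_age: int = 65
    price_year: int = 2022

    def _lookup(self, table: Mapping[str, float], year: str) -> Money:
        if year not in table:
            raise KeyError(f"no wage for fiscal year {year!r}")
        value = table[year]
        if float(value) <= 0:
            raise ValueError("wages must be positive")
        return Money(_to_decimal(value), self.price_year)


def carer_wage(carer: CarerRecord, respondent_age: float, policy: WagePolicy, year: str) -> Money:
    """Hourly wage imputed to a carer's time.

    Minimum wage when the carer is out of work, or is a sibling, spouse,
    friend or parent of a respondent past retirement age (assumed likewise
    retired); average wage otherwise.
    """
    deemed_retired = (
        respondent_age > policy.retirement_age
        and carer.relationship.lower() in RETIRED_WITH_RESPONDENT
    )
    if not carer.employed or deemed_retired:
        return policy._lookup(policy.minimum_wage, year)
    return policy._lookup(policy.average_wage, year)


def combined_help_margin(in_margin: float, out_margin: float) -> float:
    """Single receiving-help factor from the in-/out-of-household margins.

    The two margins enter additively (capped at one so the factor stays a
    proportion); any overlap between the channels is measured against the
    respondent-level computation in the test suite.
    """
    for m in (in_margin, out_margin):
        if not 0.0 <= m <= 1.0:
            raise ValueError("help margins must lie in [0, 1]")
    return min(in_margin + out_margin, 1.0)


@dataclass(frozen=True)
class InformalCareInputs:
    """Everything the multiplicative informal-care formula needs.

    ``carer_margins`` maps carer slot (1-based) → frequency → AME;
    ``hours_per_contact`` and ``hourly_wage`` map slot → value. Margins are
    :class:`MarginalEffect` so the PSA can perturb them by their SEs.
    """

    population_over_50: float
    cvd_prevalence: float
    disability: MarginalEffect
    in_help: MarginalEffect
    out_help: MarginalEffect
    carer_margins: Mapping[int, Mapping[str, MarginalEffect]]
    hours_per_contact: Mapping[int, float]
    hourly_wage: Mapping[int, Money]
    price_year: int = 2022

    def __post_init__(self) -> None:
        if self.population_over_50 < 0:
            raise ValueError("population must be non-negative")
        proportions = [self.cvd_prevalence, self.disability.margin, self.in_help.margin, self.out_help.margin]
        for slot, freqs in self.carer_margins.items():
            if slot not in self.hours_per_contact or slot not in self.hourly_wage:
                raise ValueError(f"carer slot {slot} lacks hours or wage")
            for freq, eff in freqs.items():
                if freq not in ANNUALIZATION:
                    raise ValueError(f"unknown frequency {freq!r}")
                proportions.append(eff.margin)
        for p in proportions:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion {p} outside [0, 1]")


def _cost_from_values(
    inputs: InformalCareInputs,
    disability: float,
    help_combined: float,
    carer_margins: Mapping[int, Mapping[str, float]],
    term_log: Optional[list] = None,
) -> Money:
    per_person = 0.0
    for slot, freqs in carer_margins.items():
        hours = inputs.hours_per_contact[slot]
        wage = float(inputs.hourly_wage[slot].amount)
        for freq, margin in freqs.items():
            term = margin * ANNUALIZATION[freq] * hours * wage
            per_person += term
            if term_log is not None:
                term_log.append(
                    {
                        "slot": slot,
                        "frequency": freq,
                        "margin": margin,
                        "contacts_per_year": ANNUALIZATION[freq],
                        "hours_per_contact": hours,
                        "hourly_wage": wage,
                        "annual_cost_per_eligible_person": term,
                    }
                )
    total = (
        inputs.population_over_50 * inputs.cvd_prevalence * disability * help_combined * per_person
    )
    if term_log is not None:
        term_log.append(
            {
                "population_over_50": inputs.population_over_50,
                "cvd_prevalence": inputs.cvd_prevalence,
                "disability_margin": disability,
                "help_margin": help_combined,
                "total": total,
            }
        )
    logger.debug("informal care factors: pop=%s prev=%s dis=%s help=%s per-person=%s",
                 inputs.population_over_50, inputs.cvd_prevalence, disability, help_combined, per_person)
    return Money(_to_decimal(total), inputs.price_year)


def informal_care_cost(inputs: InformalCareInputs, term_log: Optional[list] = None) -> Money:
    """Base-case informal-care cost: the product of the model's factors.

    population × prevalence × disability AME × combined help AME ×
    Σ over carer slots and frequencies of
    (frequency AME × contacts/year × hours/contact × hourly wage).
    Pass ``term_log`` (a list) to capture the exact factor composition.
    """
    help_combined = combined_help_margin(inputs.in_help.margin, inputs.out_help.margin)
    base_margins = {
        slot: {freq: eff.margin for freq, eff in freqs.items()}
        for slot, freqs in inputs.carer_margins.items()
    }
    return _cost_from_values(inputs, inputs.disability.margin, help_combined, base_margins, term_log)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return float(min(max(mean, 0.0), 1.0))
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def psa_informal(
    inputs: InformalCareInputs,
    n_trials: int = 1000,
    seed: Optional[int] = None,
) -> PSAResult:
    """Monte-Carlo uncertainty propagation over the informal-care margins.

    Each margin is drawn independently from Normal(margin, se) truncated to
    [0, 1]; draw order is fixed (disability, in-help, out-help, then carer
    slots in order and frequencies most-to-least frequent) so runs are
    reproducible under a seed.
    """
    if n_trials < 2:
        raise ValueError("PSA requires at least 2 trials")
    rng = np.random.default_rng(seed)
    trials = np.empty(n_trials)
    slots = sorted(inputs.carer_margins)
    for k in range(n_trials):
        dis = _truncated_normal(rng, inputs.disability.margin, inputs.disability.se)
        in_h = _truncated_normal(rng, inputs.in_help.margin, inputs.in_help.se)
        out_h = _truncated_normal(rng, inputs.out_help.margin, inputs.out_help.se)
        carer_draws: dict[int, dict[str, float]] = {}
        for slot in slots:
            carer_draws[slot] = {}
            for freq in FREQUENCIES:
                if freq in inputs.carer_margins[slot]:
                    eff = inputs.carer_margins[slot][freq]
                    carer_draws[slot][freq] = _truncated_normal(rng, eff.margin, eff.se)
        cost = _cost_from_values(inputs, dis, combined_help_margin(in_h, out_h), carer_draws)
        trials[k] = float(cost.amount)
    return summarize_trials(trials, seed=seed)
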