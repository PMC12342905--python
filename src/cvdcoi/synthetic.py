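"""Synthetic input generators and the packaged in-study fixture bundle.

Every generator is deterministic under its seed and returns the data
together with the ground truth implied by its own parameters (analytic
average marginal effects, the true transition matrix, closed-form
present-value totals), so downstream estimators can be tested by
parameter recovery without re-deriving the truth.

The survey generator emulates the structure of a European ageing survey:
respondents over 50 with demographics, CVD flags, disability/help
indicators drawn from logistic models, and up to three carers whose
contact frequency (none/annually/monthly/weekly/daily) follows ordered
logistic models. Carer slots are hierarchical: slot k is only occupied
when slot k−1 is.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .apportionment import RuleRegistry
from .informal import FREQUENCY_ORDER, MarginalEffect
from .ledger import CostLedger
from .markov import TransitionCounts, TransitionMatrix
from .money import Money, _to_decimal
from .productivity import DeathRecord, LaborMarketTable

__all__ = [
    "SurveyGeneratorConfig",
    "LaborDeathsConfig",
    "FixtureBundle",
    "FixtureIntegrityError",
    "gen_survey",
    "gen_stroke_counts",
    "gen_labor_and_deaths",
    "load_fixtures",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class LogitCoefficients:
    """Coefficients of a binary-outcome logistic model on survey covariates.

    Age enters centred at 70 and scaled per decade; household size centred
    at 2 (0 disables the term, matching outcomes fitted without it).
    """

    intercept: float
    cvd: float
    age_per_decade: float
    gender: float
    comorbidities: float
    household_size: float = 0.0

    def linear_predictor(self, cov: "Covariates", cvd: np.ndarray) -> np.ndarray:
        lp = (
            self.intercept
            + self.cvd * cvd
            + self.age_per_decade * (cov.age - 70.0) / 10.0
            + self.gender * cov.gender
            + self.comorbidities * cov.comorbidities
            + self.household_size * (cov.household_size - 2.0)
        )
        return lp


@dataclass(frozen=True)
class OrderedCoefficients:
    """Ordered-logit latent-scale coefficients and cutpoints for one carer slot."""

    cvd: float
    age_per_decade: float
    comorbidities: float
    household_size: float
    cutpoints: tuple  # len = n_categories - 1, increasing

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutpoints)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        object.__setattr__(self, "cutpoints", cuts)

    def latent(self, cov: "Covariates", cvd: np.ndarray) -> np.ndarray:
        return (
            self.cvd * cvd
            + self.age_per_decade * (cov.age - 70.0) / 10.0
            + self.comorbidities * cov.comorbidities
            + self.household_size * (cov.household_size - 2.0)
        )

    def category_probs(self, cov: "Covariates", cvd: np.ndarray) -> np.ndarray:
        """(n, n_categories) probabilities, lowest category first."""
        u = self.latent(cov, cvd)
        cdf = _sigmoid(np.asarray(self.cutpoints)[None, :] - u[:, None])
        n_cat = len(self.cutpoints) + 1
        probs = np.empty((len(u), n_cat))
        probs[:, 0] = cdf[:, 0]
        for k in range(1, n_cat - 1):
            probs[:, k] = cdf[:, k] - cdf[:, k - 1]
        probs[:, -1] = 1.0 - cdf[:, -1]
        return probs


@dataclass
class Covariates:
    age: np.ndarray
    gender: np.ndarray
    comorbidities: np.ndarray
    household_size: np.ndarray


@dataclass(frozen=True)
class SurveyGeneratorConfig:
    """Sample size, prevalence and true model coefficients for gen_survey.

    Defaults target marginal-effect magnitudes in the range reported for
    real ageing-survey data (disability AME ≈ 0.145).
    """

    n: int = 20_000
    cvd_prevalence: float = 0.35
    seed: int = 0
    disability: LogitCoefficients = LogitCoefficients(-2.2, 0.9, 0.4, -0.2, 0.35)
    in_help: LogitCoefficients = LogitCoefficients(-2.6, 0.85, 0.35, -0.1, 0.3, -0.15)
    out_help: LogitCoefficients = LogitCoefficients(-1.6, 1.15, 0.35, -0.1, 0.3, -0.15)
    carer_slots: tuple = (
        OrderedCoefficients(0.8, 0.3, 0.15, -0.1, (0.9, 1.7, 2.5, 3.5)),
        OrderedCoefficients(0.8, 0.3, 0.15, -0.1, (1.7, 2.4, 3.1, 4.0)),
        OrderedCoefficients(0.8, 0.3, 0.15, -0.1, (2.4, 3.0, 3.6, 4.4)),
    )
    mean_log_hours: float = 0.7
    sd_log_hours: float = 0.5
    carer_employed_prob: float = 0.6

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.cvd_prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        for coeffs in (self.disability, self.in_help, self.out_help):
            if not np.isfinite(
                [coeffs.intercept, coeffs.cvd, coeffs.age_per_decade, coeffs.gender,
                 coeffs.comorbidities, coeffs.household_size]
            ).all():
                raise ValueError("logit coefficients must be finite")


_RELATIONSHIPS = np.array(["child", "spouse", "friend", "neighbour", "sibling", "other"])
_RELATIONSHIP_P = np.array([0.40, 0.20, 0.12, 0.10, 0.08, 0.10])


def gen_survey(config: SurveyGeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate survey microdata and the analytic truth implied by the config.

    Returns ``(frame, truth)`` where ``truth`` carries the analytic AMEs
    (sample-averaged true-model probability contrasts with the CVD flag
    switched): ``truth['ame'][outcome]`` for the binary outcomes and
    ``truth['ordered_ame'][slot][category]`` for each carer slot
    (unconditional on the hierarchical slot occupancy).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    cov = Covariates(
        age=rng.uniform(51.0, 90.0, n),
        gender=rng.binomial(1, 0.55, n).astype(float),
        comorbidities=np.clip(rng.poisson(1.5, n), 0, 8).astype(float),
        household_size=(1 + rng.poisson(0.8, n)).astype(float),
    )
    cvd = rng.binomial(1, config.cvd_prevalence, n).astype(float)

    frame = pd.DataFrame(
        {
            "age": cov.age,
            "gender": cov.gender.astype(int),
            "n_comorbidities": cov.comorbidities.astype(int),
            "household_size": cov.household_size.astype(int),
            "has_cvd": cvd.astype(int),
        }
    )

    truth: dict = {"ame": {}, "ordered_ame": {}, "config": config}
    ones = np.ones(n)
    zeros = np.zeros(n)
    for name, coeffs in (
        ("severely_disabled", config.disability),
        ("in_household_help", config.in_help),
        ("out_household_help", config.out_help),
    ):
        p = _sigmoid(coeffs.linear_predictor(cov, cvd))
        frame[name] = rng.binomial(1, p)
        p1 = _sigmoid(coeffs.linear_predictor(cov, ones))
        p0 = _sigmoid(coeffs.linear_predictor(cov, zeros))
        truth["ame"][name] = float(np.mean(p1 - p0))

    prev_present = np.ones(n, dtype=bool)
    for slot_idx, coeffs in enumerate(config.carer_slots, start=1):
        probs = coeffs.category_probs(cov, cvd)
        u = rng.uniform(size=n)
        cum = np.cumsum(probs, axis=1)
        cats = (u[:, None] > cum).sum(axis=1)  # index into FREQUENCY_ORDER
        cats = np.where(prev_present, cats, 0)  # hierarchical: no gaps
        labels = np.array(FREQUENCY_ORDER, dtype=object)[cats]
        frame[f"carer{slot_idx}_freq"] = labels
        present = cats > 0
        hours = np.where(
            present, np.exp(rng.normal(config.mean_log_hours, config.sd_log_hours, n)), np.nan
        )
        frame[f"carer{slot_idx}_hours"] = hours
        rel = rng.choice(_RELATIONSHIPS, size=n, p=_RELATIONSHIP_P)
        frame[f"carer{slot_idx}_relationship"] = np.where(present, rel, "")
        employed = rng.binomial(1, config.carer_employed_prob, n).astype(float)
        frame[f"carer{slot_idx}_employed"] = np.where(present, employed, np.nan)
        p1 = coeffs.category_probs(cov, ones)
        p0 = coeffs.category_probs(cov, zeros)
        truth["ordered_ame"][slot_idx] = {
            cat: float(np.mean(p1[:, k] - p0[:, k])) for k, cat in enumerate(FREQUENCY_ORDER)
        }
        prev_present = present

    return frame, truth


def gen_stroke_counts(
    n_patients: Union[int, Mapping[str, int]],
    true_matrix: TransitionMatrix,
    seed: Optional[int] = None,
    absorbing: Sequence[str] = ("death",),
) -> TransitionCounts:
    """Multinomial transition counts per from-state under a known matrix.

    ``n_patients`` is either one count applied to every non-absorbing
    state or a mapping state → count. Absorbing states get zero rows.
    """
    rng = np.random.default_rng(seed)
    states = true_matrix.states
    counts = np.zeros_like(true_matrix.probabilities)
    absorbing_set = set(absorbing)
    for i, state in enumerate(states):
        if state in absorbing_set:
            continue
        n_row = n_patients[state] if isinstance(n_patients, Mapping) else int(n_patients)
        if n_row < 0:
            raise ValueError("row sample sizes must be non-negative")
        if n_row:
            counts[i] = rng.multinomial(n_row, true_matrix.probabilities[i])
    return TransitionCounts(states, counts)


@dataclass(frozen=True)
class LaborDeathsConfig:
    """Shape parameters for the synthetic deaths / labour-market tables.

    ``flat`` freezes employment and wages at single values across all
    ages, which makes the human-capital present value available in closed
    form (a geometric annuity) for oracle tests.
    """

    total_deaths: int = 20_000
    band_width: int = 5
    age_low: int = 15
    age_high: int = 90
    male_share: float = 0.55
    death_age_slope: float = 0.08  # exponential rise of death counts with age
    flat: bool = False
    flat_employment_rate: float = 0.8
    flat_annual_wage: float = 30_000.0
    price_year: int = 2022


def gen_labor_and_deaths(
    config: LaborDeathsConfig = LaborDeathsConfig(), seed: Optional[int] = None
) -> tuple[list[DeathRecord], LaborMarketTable]:
    """Age-increasing CVD death counts and a hump-shaped labour market.

    Employment rates rise through the 20s, plateau mid-career and fall
    toward retirement; wages peak in the late 40s. Deterministic under the
    seed (death counts are Poisson draws around the exponential age curve).
    """
    rng = np.random.default_rng(seed)
    bands = [
        (lo, min(lo + config.band_width, config.age_high))
        for lo in range(config.age_low, config.age_high, config.band_width)
    ]
    mids = np.array([(lo + hi) / 2 for lo, hi in bands])
    weights = np.exp(config.death_age_slope * (mids - config.age_low))
    weights /= weights.sum()

    deaths: list[DeathRecord] = []
    for (lo, hi), w in zip(bands, weights):
        expected = config.total_deaths * w
        for sex, share in (("male", config.male_share), ("female", 1 - config.male_share)):
            count = int(rng.poisson(expected * share)) if expected > 0 else 0
            deaths.append(DeathRecord(age_low=lo, age_high=hi, sex=sex, deaths=count))

    rows = []
    for lo, hi in bands:
        mid = (lo + hi) / 2
        if config.flat:
            for sex in ("male", "female"):
                rows.append((sex, lo, hi, config.flat_employment_rate, config.flat_annual_wage))
            continue
        emp = 0.85 * np.exp(-(((mid - 40.0) / 22.0) ** 2))
        for sex, premium in (("male", 1.05), ("female", 0.95)):
            wage = 24_000.0 + 16_000.0 * np.exp(-(((mid - 48.0) / 14.0) ** 2))
            rows.append((sex, lo, hi, float(min(max(emp, 0.0), 1.0)), float(wage * premium)))
    table = LaborMarketTable(rows, price_year=config.price_year)
    return deaths, table


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


@dataclass(frozen=True)
class FixtureBundle:
    """The packaged cost tables, margins and constants registry."""

    direct: CostLedger
    indirect: CostLedger
    ehn2015: CostLedger
    printed_totals: pd.DataFrame
    margins: pd.DataFrame
    rules: RuleRegistry
    constants: dict

    def printed_total(self, quantity: str, fiscal_year: str) -> Money:
        sub = self.printed_totals[
            (self.printed_totals["quantity"] == quantity)
            & (self.printed_totals["fiscal_year"] == fiscal_year)
        ]
        if len(sub) != 1:
            raise KeyError(f"no printed total for ({quantity!r}, {fiscal_year!r})")
        return Money(_to_decimal(str(sub.iloc[0]["amount_gbp"])), int(self.constants["price_year"]))

    def margin_effect(self, outcome: str, category: str = "") -> MarginalEffect:
        sub = self.margins[
            (self.margins["outcome"] == outcome) & (self.margins["category"].fillna("") == category)
        ]
        if len(sub) != 1:
            raise KeyError(f"no margin row for ({outcome!r}, {category!r})")
        row = sub.iloc[0]
        return MarginalEffect(
            margin=float(row["margin"]),
            se=float(row["se"]),
            ci_low=float(row["ci_low"]),
            ci_high=float(row["ci_high"]),
            pseudo_r2=float(row["pseudo_r2"]),
        )


def _read_checked(name: str, checksums: Mapping[str, str]) -> bytes:
    payload = resources.files("cvdcoi.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    if checksums.get(name) != digest:
        raise FixtureIntegrityError(f"fixture {name!r} failed its checksum")
    return payload


def load_fixtures() -> FixtureBundle:
    """Load and integrity-check the packaged fixture bundle."""
    import io

    checksums = json.loads(resources.files("cvdcoi.data").joinpath("checksums.json").read_text())

    def frame(name: str) -> pd.DataFrame:
        return pd.read_csv(io.BytesIO(_read_checked(name, checksums)), dtype={"amount_gbp": str})

    direct = CostLedger.from_frame(frame("direct_costs.csv"))
    indirect = CostLedger.from_frame(frame("indirect_costs.csv"))
    ehn2015 = CostLedger.from_frame(frame("ehn2015_costs.csv"), allow_aggregate_nation=True)
    printed = frame("uk_printed_totals.csv")
    margins = pd.read_csv(
        io.BytesIO(_read_checked("table4_margins.csv", checksums)),
        dtype={"category": str},
        keep_default_na=False,
    )
    rules = RuleRegistry._from_mapping(
        yaml.safe_load(_read_checked("apportionment_rules.yaml", checksums))
    )
    constants = yaml.safe_load(_read_checked("constants.yaml", checksums))
    return FixtureBundle(
        direct=direct,
        indirect=indirect,
        ehn2015=ehn2015,
        printed_totals=printed,
        margins=margins,
        rules=rules,
        constants=constants,
    )
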