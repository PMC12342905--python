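# Methods

This note documents the models implemented in `cvdcoi`, the conventions
and defaults chosen where the underlying methodology left the design
open, and what the synthetic-data evidence does and does not establish.

## Scope and structure

The pipeline estimates the societal cost of cardiovascular disease (CVD)
in the UK for the fiscal years 2019/20–2021/22, in 2022 real terms, as
eleven cost components: eight direct (inpatient, outpatient, A&E,
primary care, medications, devices, and long-term care split into
post-stroke and vascular-dementia parts) and three indirect (morbidity,
mortality, informal care). Five components are modelled (primary care,
both long-term-care parts, the two productivity losses, informal care);
the rest are read from published aggregates. Intangible (quality-of-life)
costs are out of scope.

## Money and aggregation

Amounts are `decimal.Decimal` at full precision, tagged with a price
year. Arithmetic across price years is rejected rather than coerced;
series are restated with GDP-deflator ratios first. Rounding happens only
at report time (pennies half-up; headlines in £bn to 3 dp half-up).

The packaged cost tables store one penny-rounded value per
(component, nation, year) cell. Because each cell was rounded
independently at publication, a derived sum over four nations or ~10
components can differ from the independently rounded printed total by a
cent or two; the test suite therefore asserts identity within £0.02
rather than exactly. One printed growth figure for medications (15.3%)
is not consistent with the published cells, which give 15.2% and a fall
of exactly £348,272,852.85; the package reproduces the cells and reports
the recomputed percentage, leaving the discrepancy documented rather
than reconciled.

The UK row of any table is always derived by aggregation. The single
exception is the 2015 comparison ledger, which exists only as UK
aggregates and must be opened explicitly with
`allow_aggregate_nation=True`.

## Top-down apportionment

All attribution shares live in a versioned YAML registry
(`cvdcoi/data/apportionment_rules.yaml`), not in code, because the
sensitivity analysis varies them: generalist case-mix 17.9%,
stroke/TIA-to-neurology 30%, vascular-to-general-surgery 7.2%,
primary-care hypertension proxy 12%, vascular-dementia share 17%.
Fractional attributed counts stay fractional until costing. Where both
uncoded-activity attribution and the generalist share apply, coding
attribution is applied first. Wales publishes only a gross circulatory
secondary-care budget; the outpatient and A&E components are backed out
by England-derived ratios and the inpatient cost is the residual, so the
three Welsh estimates recompose the budget exactly. Internal consistency
of the published Welsh outpatient split with the England-derived ratio
holds to ~0.6% across years (tested at 1%); the residual inconsistency
is in the source table, not the arithmetic.

## Post-stroke long-term care

States default to home / community (early-supported discharge and
community rehabilitation) / care home / death; the set is configurable.
Transition probabilities are row-normalized maximum-likelihood estimates
from audit-style discharge counts; absorbing states take identity rows.
Cycles are annual with no half-cycle correction and costs accrue at
cycle start: a trace of `n_cycles` cycles accrues occupancy from rows
0..n−1. Care-home person-years are costed at a configurable unit cost
(£40,000/person-year in the synthetic pipeline). The audit state set,
cycle count and unit costs behind the published stroke figures are not
public, so the published stroke LTC totals are matched by configuration,
not asserted from first principles.

Vascular-dementia LTC cost is the 17% share applied to a total dementia
social-care cost taken as input.

For probabilistic sensitivity analysis each transition row is drawn from
a Dirichlet with the observed counts as concentrations — the conjugate
posterior under a flat prior, so better-observed rows vary less.
Structural zeros (never-observed destinations) stay exactly zero.

## Informal care

The average marginal effect (AME) of the CVD flag is the discrete
change: the sample mean of the predicted-probability difference with the
flag switched on versus off, all other covariates at observed values.
Binary outcomes (severe disability; in-/out-of-household help) use
logistic regression — disability controls for age, gender and
comorbidity count; the help outcomes add household size. Carer contact
frequency uses ordered logistic regression over
none < annually < monthly < weekly < daily. Standard errors are
delta-method (analytic gradient for the logit; central-difference
Jacobian for the ordered model); CIs use z = 1.96 exactly and are
reported at 4 dp.

The aggregate cost is the product population over 50 × CVD prevalence ×
disability AME × combined help AME × Σ over carer slots and frequencies
of (frequency AME × contacts/year × hours/contact × hourly wage), with
annualization daily = 365, weekly = 52, monthly = 12, annually = 1
contacts/year. Conventions chosen here, where the methodology is silent:

- The two help margins enter as a single additive factor capped at 1
  (`min(in + out, 1)`); the respondent-level overlap this ignores is
  measured in the test suite.
- CVD prevalence is the respondent-level union of heart attack,
  hypertension and stroke flags, not the sum of three prevalences.
- Carers are imputed the national minimum wage when out of work or when
  they are a sibling, spouse, friend or parent of a respondent past 65
  (assumed likewise retired); the average wage otherwise.
- PSA draws each margin independently from Normal(margin, SE) truncated
  to [0, 1], in a fixed order from one seeded stream.

The product of sample-mean margins is not the mean of per-respondent
products. Under homogeneous effects the two agree (verified to 1% in the
tests); under the realistic heterogeneous defaults the per-respondent
expectation exceeds the aggregate product by roughly 20% because the
discrete-change effects are positively correlated through shared age and
comorbidity covariates. This aggregation bias is inherent to the
product-of-margins construction and is measured, not corrected.

## Productivity losses

Mortality follows the human-capital approach: working age 15–64,
retirement at 65, age/sex-specific employment rates and annual wages,
discounted at 3.5% per annum. The year of death is counted undiscounted;
discounting starts the following year. Deaths are evaluated at the
integer midpoint of their age band. Employment rates and wages are held
at the analysis year, not projected. Morbidity is sickness days × the
average daily wage plus benefit claims costed as claimants × weekly
amount × weeks remaining in payment during the year; DLA dementia claims
are scaled by the 17% vascular-dementia share before costing.

## Sensitivity engine

One-way analysis varies each parameter alone to its low/high limits and
reports percentage change from base, ranked by swing. PSA draws all
parameters independently (no correlation structure) from their declared
distributions — normal (optionally truncated), beta, uniform, Dirichlet —
using one seeded stream with draw order fixed by spec order, so runs are
bit-reproducible. Quartiles use linear interpolation between order
statistics (the box-plot convention the five-number summaries assume).
A component-extremes tornado swaps one modelled component to its PSA
minimum/maximum while others stay at base.

## Synthetic data: what it shows

Generators return (data, truth) pairs: the survey generator emits the
analytic AMEs implied by its own coefficients (averaged over the drawn
covariates), the stroke generator keeps its true matrix, and the flat
labour-market configuration admits a closed-form annuity. Defaults were
chosen once to mirror realistic magnitudes — ages uniform 51–90, CVD
prevalence 0.35, disability AME ≈ 0.145, n = 20,000 — and problem sizes
in tests (20 recovery replicates at n = 20,000; 1000-trial PSAs;
10-cycle cohorts) keep the full suite under a minute while leaving
Monte-Carlo error well inside the asserted tolerances.

Limitations of the emulation: covariates are drawn independently (no
age–comorbidity correlation), outcomes follow the fitted model families
exactly (no misspecification), carer slots beyond the first are
generated hierarchically (slot k only when slot k−1 is present), so
unconditional ordered-model recovery is asserted for the first slot
only, and there are no survey weights, item nonresponse or recall error.
Passing recovery tests therefore demonstrate the estimators are correct
under the assumed model, not that the published survey-derived margins
are themselves unbiased. Likewise the published modelled totals (e.g.
PSA medians) depend on restricted inputs and are reproduced only where
they are arithmetic identities of the published tables.

## Numerical choices

- Transition-matrix rows must sum to 1 within 1e-9; cohort mass is
  conserved to the same tolerance.
- Logistic fits reject single-class outcomes and separation-like
  divergence (|coefficient| > 50); ordered fits drop never-observed
  categories (their thresholds are unidentified).
- Ordered-model delta SEs use central differences with step
  1e-6·max(1, |θ|).
- Empty aggregations return an exact zero in the caller-supplied price
  year.
- Dirichlet sampling requires at least one observed transition per
  non-absorbing row; single-destination rows are degenerate at 1.
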