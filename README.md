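# cvdcoi

Cost-of-illness (COI) modelling for cardiovascular disease (CVD) in the
United Kingdom, built for health economists and epidemiologists who need a
tested, reusable implementation of a societal-perspective COI pipeline
rather than a spreadsheet. The package re-implements, as a library, every
stage of a UK CVD costing exercise for the fiscal years 2019/20–2021/22:

- **Cost ledger** (`cvdcoi.ledger`) — exact-decimal GBP amounts tagged by
  cost component, nation and fiscal year, with GDP-deflator inflation,
  currency conversion and 3.5%-per-annum discounting. Sums close to the
  penny; price-year mismatches are hard errors.
- **Top-down apportionment** (`cvdcoi.apportionment`) — the share, ratio
  and residual rules that attribute aggregate NHS spending to CVD
  (generalist case-mix 17.9%, stroke/TIA-to-neurology 30%,
  vascular-to-general-surgery 7.2%, primary-care hypertension proxy 12%,
  population scaling, Welsh budget residuals), loaded from a versioned
  registry.
- **Long-term care** (`cvdcoi.markov`) — a post-stroke Markov cohort model
  (home / community / care home / death, annual cycles) costed per
  care-home person-year, plus the 17% vascular-dementia share of dementia
  social-care costs, with Dirichlet transition uncertainty for PSA.
- **Informal care** (`cvdcoi.informal`) — average marginal effects (AMEs)
  of CVD from logistic and ordered-logistic regressions on ageing-survey
  microdata, composed multiplicatively with carer hours and imputed wages.
- **Productivity losses** (`cvdcoi.productivity`) — human-capital present
  value of earnings to retirement at 65 for premature mortality, and
  sickness absence plus ESA/DLA benefit payments for morbidity.
- **Sensitivity engine** (`cvdcoi.sensitivity`) — generic one-way
  (tornado) and probabilistic (Monte Carlo) analysis over any cost model.
- **Synthetic data** (`cvdcoi.synthetic`) — seeded generators for survey
  microdata, stroke transition counts and deaths/labour tables, each
  returning its own analytic ground truth; plus the packaged published
  cost tables used as fixtures.

## The models in brief

For a binary outcome (e.g. severe disability) fitted by logistic
regression with CVD flag $d$ and covariates $x$, the AME is the discrete
change averaged over the sample,

$$\mathrm{AME} = \tfrac1n \sum_i \left[\sigma(\beta_0 + \beta_d + x_i'\beta) - \sigma(\beta_0 + x_i'\beta)\right],$$

with delta-method standard errors and CIs at margin ± 1.96·SE. Informal
care costs are the product population × prevalence × disability AME ×
help AME × Σ (frequency AME × contacts/year × hours × wage).

A death at age $a$ costs the discounted earnings stream
$\sum_{y=a}^{64} e(y)\,w(y)\,(1.035)^{-(y-a)}$ with age/sex-specific
employment rates $e$ and wages $w$ (year of death undiscounted).

The stroke cohort trace follows $n_{t+1} = n_t P$ with $P$ the
row-normalized audit transition counts; care-home occupancy accrues
person-years at cycle start and is costed at a per-person-year unit cost.

## Worked example

```bash
python examples/fixture_report.py
```

prints

```
Headline cost of CVD in the UK, 2021/22 (2022 prices, GBP bn):
     direct: 16.620
   indirect: 12.402
      total: 29.021

Inpatient care grew 23.5% since the 2015 baseline
Long-term care + devices (newly costed components) add £5.053 bn
Direct costs are 7.3% of UK public health spending
```

i.e. the total societal cost of CVD in 2021/22 is £29.021 bn, of which
£16.620 bn is direct care spending (inpatient care the largest component)
and £12.402 bn indirect losses (informal care the largest); the newly
costed long-term-care and device components add £5.053 bn that earlier
UK costings omitted. The other scripts in `examples/` walk through each
modelled component: `informal_care.py` (survey AMEs → cost → PSA),
`stroke_ltc.py` (Markov cohort → person-years → Dirichlet PSA),
`mortality_losses.py` (human-capital present values) and
`sensitivity_analysis.py` (tornado and Monte Carlo tables).

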