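"""Human-capital production losses from premature CVD mortality.

Generates synthetic deaths-by-age-band and labour-market tables, values
each death as the discounted earnings stream to retirement at 65, and
perturbs wages/employment in a Monte Carlo sensitivity run.
"""

from cvdcoi.money import discount_factor
from cvdcoi.productivity import mortality_loss, present_value_earnings, psa_mortality
from cvdcoi.synthetic import LaborDeathsConfig, gen_labor_and_deaths

deaths, labor = gen_labor_and_deaths(LaborDeathsConfig(total_deaths=20_000, age_high=65), seed=31)

pv40 = present_value_earnings(40, "female", labor)
print(f"Present value of earnings lost for a death at 40 (female): £{float(pv40.amount):,.0f}")
print(f"Discount factor 10 years ahead at 3.5%: {discount_factor(10):.4f}")

loss = mortality_loss(deaths, labor)
print(f"Mortality production loss over {sum(d.deaths for d in deaths):,.0f} deaths: "
      f"£{loss.in_billions()} bn")

psa = psa_mortality(deaths, labor, wage_rel_sd=0.05, employment_rel_sd=0.02, n=1000, seed=31)
print(f"PSA median £{psa.median / 1e9:.3f} bn (IQR {psa.q25 / 1e9:.3f}-{psa.q75 / 1e9:.3f})")
# Earnings in the year of death are undiscounted; later years shrink by
# 1.035^-t. Deaths at or past 65 contribute nothing under the human-capital
# convention with retirement at 65.
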