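# Analysis-wide constants.
price_year: 2022
discount_rate: 0.035          # HM Treasury recommended annual rate
retirement_age: 65
working_age_start: 15
uk_public_health_spending:    # total public UK healthcare spending, GBP, 2022 real terms
  "2021/22": 228289000000
annualization:                # contacts per year by carer contact frequency
  daily: 365
  weekly: 52
  monthly: 12
  annually: 1
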