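"""Post-stroke long-term-care costs from a Markov cohort model.

Simulates audit-style discharge-destination counts, converts them to
transition probabilities, runs an annual-cycle cohort for a decade and
costs the care-home person-years; then quantifies transition-probability
uncertainty with Dirichlet PSA draws.
"""

import numpy as np

from cvdcoi.markov import (
    DEFAULT_STATES,
    MarkovModel,
    TransitionMatrix,
    care_home_person_years,
    counts_to_probabilities,
    psa_stroke_ltc,
    run_cohort,
    stroke_ltc_cost,
    vad_ltc_cost,
)
from cvdcoi.money import Money
from cvdcoi.synthetic import gen_stroke_counts

true_matrix = TransitionMatrix(
    DEFAULT_STATES,
    np.array(
        [
            [0.80, 0.08, 0.04, 0.08],
            [0.30, 0.45, 0.15, 0.10],
            [0.00, 0.00, 0.75, 0.25],
            [0.00, 0.00, 0.00, 1.00],
        ]
    ),
)
counts = gen_stroke_counts(2_000, true_matrix, seed=23)
matrix = counts_to_probabilities(counts)
model = MarkovModel(matrix)

cohort = [59_500.0, 20_400.0, 5_100.0, 0.0]  # one year of stroke discharges
trace = run_cohort(model, cohort, n_cycles=10)
person_years = care_home_person_years(trace, model)
unit_cost = Money(40_000, 2022)
cost = stroke_ltc_cost(person_years, unit_cost)
print(f"Care-home person-years over 10 annual cycles: {person_years:,.0f}")
print(f"Stroke LTC cost at £{unit_cost.amount}/person-year: £{cost.in_billions()} bn")

psa = psa_stroke_ltc(counts, cohort, n_cycles=10, unit_cost=unit_cost, n_trials=1000, seed=23)
print(f"PSA median £{psa.median / 1e9:.3f} bn "
      f"(IQR {psa.q25 / 1e9:.3f}-{psa.q75 / 1e9:.3f}, range {psa.minimum / 1e9:.3f}-{psa.maximum / 1e9:.3f})")

vad = vad_ltc_cost(Money(11_200_000_000, 2022), 0.17)
print(f"Vascular dementia at 17% of £11.2 bn dementia social care: £{vad.in_billions()} bn")
# Person-years accrue at cycle start with no half-cycle correction; the PSA
# redraws each transition row from a Dirichlet with the observed counts as
# concentrations, so better-observed rows vary less.
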