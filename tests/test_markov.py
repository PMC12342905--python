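"""Stroke pathway Markov cohort model and the vascular-dementia share."""

from decimal import Decimal

import numpy as np
import pytest

from cvdcoi.markov import (
    DEFAULT_STATES,
    MarkovModel,
    TransitionCounts,
    TransitionMatrix,
    care_home_person_years,
    counts_to_probabilities,
    psa_stroke_ltc,
    run_cohort,
    sample_transition_matrix,
    stroke_ltc_cost,
    vad_ltc_cost,
)
from cvdcoi.money import FiscalYear, Money, Nation, CostComponent

THREE_STATES = ("well", "care_home", "death")


def three_state_counts(counts=((70, 20, 10), (0, 80, 20), (0, 0, 0))):
    return TransitionCounts(THREE_STATES, np.array(counts, dtype=float))


class TestCountsToProbabilities:
    def test_row_normalization(self):
        counts = TransitionCounts(("a", "b"), np.array([[8.0, 2.0], [0.0, 5.0]]))
        matrix = counts_to_probabilities(counts, absorbing=("b",))
        assert matrix.probabilities[0] == pytest.approx([0.8, 0.2])

    def test_boundary_all_mass_one_destination(self):
        counts = TransitionCounts(("a", "b"), np.array([[5.0, 0.0], [0.0, 3.0]]))
        matrix = counts_to_probabilities(counts, absorbing=("b",))
        assert matrix.probabilities[0] == pytest.approx([1.0, 0.0])

    def test_rows_sum_to_one(self):
        matrix = counts_to_probabilities(three_state_counts(), absorbing=("death",))
        assert matrix.probabilities.sum(axis=1) == pytest.approx([1.0, 1.0, 1.0])

    def test_zero_count_non_absorbing_rejected(self):
        counts = TransitionCounts(("a", "b"), np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="no observed transitions"):
            counts_to_probabilities(counts, absorbing=())

    def test_absorbing_state_gets_identity_row(self):
        matrix = counts_to_probabilities(three_state_counts(), absorbing=("death",))
        assert matrix.probabilities[2] == pytest.approx([0.0, 0.0, 1.0])


class TestRunCohort:
    def test_identity_matrix_constant_occupancy(self):
        matrix = TransitionMatrix(("a", "b"), np.eye(2))
        model = MarkovModel(matrix, absorbing=())
        trace = run_cohort(model, [30.0, 70.0], 5)
        assert np.allclose(trace, [[30.0, 70.0]] * 6)

    def test_certain_death_absorbs_in_one_cycle(self):
        matrix = TransitionMatrix(
            THREE_STATES, np.array([[0, 0, 1.0], [0, 0, 1.0], [0, 0, 1.0]])
        )
        model = MarkovModel(matrix, absorbing=())
        trace = run_cohort(model, [50.0, 50.0, 0.0], 3)
        assert trace[1] == pytest.approx([0, 0, 100.0])

    def test_matches_matrix_power_oracle(self):
        matrix = counts_to_probabilities(three_state_counts(), absorbing=("death",))
        model = MarkovModel(matrix)
        initial = np.array([1000.0, 0.0, 0.0])
        trace = run_cohort(model, initial, 5)
        for t in range(6):
            expected = initial @ np.linalg.matrix_power(matrix.probabilities, t)
            assert np.abs(trace[t] - expected).max() < 1e-12

    def test_mass_conserved_and_death_monotone(self):
        matrix = counts_to_probabilities(three_state_counts(), absorbing=("death",))
        model = MarkovModel(matrix)
        trace = run_cohort(model, [800.0, 150.0, 50.0], 30)
        assert np.abs(trace.sum(axis=1) - 1000.0).max() < 1e-9
        deaths = trace[:, 2]
        assert np.all(np.diff(deaths) >= -1e-12)

    def test_dimension_mismatch_rejected(self):
        matrix = TransitionMatrix(("a", "b"), np.eye(2))
        with pytest.raises(ValueError):
            run_cohort(MarkovModel(matrix, absorbing=()), [1.0, 2.0, 3.0], 2)


class TestPersonYears:
    def model(self):
        matrix = counts_to_probabilities(three_state_counts(), absorbing=("death",))
        return MarkovModel(matrix)

    def test_zero_occupancy_zero_person_years(self):
        trace = np.zeros((4, 3))
        assert care_home_person_years(trace, self.model(), "care_home") == 0.0

    def test_constant_occupancy_three_cycles(self):
        trace = np.full((4, 3), 100.0)  # 3 cycles simulated
        assert care_home_person_years(trace, self.model(), "care_home") == pytest.approx(300.0)

    def test_linear_decay_equals_hand_sum(self):
        occupancies = [100.0, 80.0, 60.0, 40.0, 20.0]
        trace = np.zeros((5, 3))
        trace[:, 1] = occupancies
        expected = sum(occupancies[:-1])  # cycle-start accrual over 4 cycles
        assert care_home_person_years(trace, self.model(), "care_home") == pytest.approx(expected)

    def test_unknown_state_rejected(self):
        with pytest.raises(KeyError):
            care_home_person_years(np.zeros((2, 3)), self.model(), "hospice")


class TestLtcCosts:
    def test_zero_person_years(self):
        assert stroke_ltc_cost(0.0, Money(40_000, 2022)).amount == 0

    def test_product(self):
        assert stroke_ltc_cost(1000.0, Money(40_000, 2022)).amount == Decimal(40_000_000)

    def test_vad_share_arithmetic(self):
        assert vad_ltc_cost(Money(1000, 2022), 0.17).amount == Decimal("170.00")
        assert vad_ltc_cost(Money(1000, 2022), 0.0).amount == 0

    def test_vad_share_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vad_ltc_cost(Money(1000, 2022), 1.5)

    def test_vad_back_solve_round_trip_on_fixture(self, fixtures):
        cell = fixtures.direct.get(
            CostComponent.LTC_VAD, Nation.ENGLAND, FiscalYear.parse("2021/22")
        ).value
        implied_dementia_total = cell * (1 / Decimal("0.17"))
        again = vad_ltc_cost(implied_dementia_total, 0.17)
        assert abs(again.amount - cell.amount) < Decimal("1e-6")


class TestDirichletSampling:
    def test_seed_reproducibility(self):
        counts = three_state_counts()
        a = sample_transition_matrix(counts, 7)
        b = sample_transition_matrix(counts, 7)
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_huge_counts_concentrate_on_mle(self):
        counts = three_state_counts(((70e6, 20e6, 10e6), (0, 80e6, 20e6), (0, 0, 0)))
        mle = counts_to_probabilities(three_state_counts(), absorbing=("death",))
        sampled = sample_transition_matrix(counts, 11)
        assert np.abs(sampled.probabilities - mle.probabilities).max() < 1e-2

    def test_mean_of_draws_approaches_mle(self):
        counts = three_state_counts()
        mle = counts_to_probabilities(counts, absorbing=("death",))
        rng = np.random.default_rng(3)
        n = 10_000
        draws = np.stack([sample_transition_matrix(counts, rng).probabilities for _ in range(n)])
        mean = draws.mean(axis=0)
        # Dirichlet marginal variance p(1-p)/(n0+1); 3 Monte-Carlo SEs
        row_totals = counts.counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            var = mle.probabilities * (1 - mle.probabilities) / (row_totals + 1)
        tol = 3 * np.sqrt(np.nan_to_num(var) / n) + 1e-12
        assert np.all(np.abs(mean - mle.probabilities) <= tol + 1e-3)

    def test_zero_count_non_absorbing_rejected(self):
        counts = TransitionCounts(("a", "b"), np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            sample_transition_matrix(counts, 1, absorbing=())


class TestStrokeLtcPsa:
    def test_summary_ordering_and_determinism(self):
        counts = three_state_counts()
        result = psa_stroke_ltc(
            counts, [1000.0, 0.0, 0.0], n_cycles=10, unit_cost=Money(40_000, 2022),
            n_trials=200, seed=5,
        )
        again = psa_stroke_ltc(
            counts, [1000.0, 0.0, 0.0], n_cycles=10, unit_cost=Money(40_000, 2022),
            n_trials=200, seed=5,
        )
        assert result.trials == again.trials
        assert result.minimum <= result.q25 <= result.median <= result.q75 <= result.maximum
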