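"""Cohort engine: conservation, absorption, discounting, comparisons."""

import warnings

import numpy as np
import pytest

from endocea.markov import (
    DEATH,
    PFS,
    ArmOutcome,
    DiscountSpec,
    StateValuation,
    TransitionMatrix,
    accumulate,
    compare,
    run_cohort,
)
from endocea.synthetic import random_scenario

LP_MATRIX = TransitionMatrix.from_probs(0.052, 0.037, 0.049)
IDENTITY = TransitionMatrix(np.eye(3))

SIMPLE_VALUATION = StateValuation(
    monthly_cost=(1000.0, 500.0, 0.0), utility=(0.8, 0.6, 0.0)
)
NO_DISCOUNT = DiscountSpec(annual_rate=0.0)


class TestTransitionMatrix:
    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TransitionMatrix(np.array([[0.9, 0.2, 0.1], [0, 0.95, 0.05], [0, 0, 1]]))

    def test_rejects_recovery_from_pd(self):
        bad = np.array([[0.9, 0.05, 0.05], [0.1, 0.85, 0.05], [0, 0, 1]])
        with pytest.raises(ValueError, match="PD->PFS"):
            TransitionMatrix(bad)

    def test_rejects_non_absorbing_death(self):
        bad = np.array([[0.9, 0.05, 0.05], [0, 0.95, 0.05], [0.5, 0, 0.5]])
        with pytest.raises(ValueError, match="absorbing"):
            TransitionMatrix(bad)


class TestRunCohort:
    def test_identity_matrix_keeps_occupancy_constant(self):
        trace = run_cohort(IDENTITY, 50)
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_geometric_series_oracle_half(self):
        # PFS-stay 0.5: person-cycles (cycle-start, incl. cycle 0) = 1/(1-0.5)
        m = TransitionMatrix.from_probs(0.25, 0.25, 0.1)
        trace = run_cohort(m, 200)
        assert trace.occupancy[:-1, PFS].sum() == pytest.approx(2.0, abs=1e-6)

    def test_geometric_series_oracle_lp(self):
        trace = run_cohort(LP_MATRIX, 600)
        assert trace.occupancy[:-1, PFS].sum() == pytest.approx(1 / (1 - 0.911), abs=1e-6)

    def test_invalid_initial_rejected(self):
        with pytest.raises(ValueError, match="distribution"):
            run_cohort(LP_MATRIX, 10, initial=(0.5, 0.2, 0.1))

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_conservation_and_absorption_on_random_scenarios(self, seed):
        spec = random_scenario(seed).build()
        for arm in spec.arms:
            trace = run_cohort(arm.matrix, 400)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            death = trace.occupancy[:, DEATH]
            assert (np.diff(death) >= -1e-12).all()
            assert death[-1] > 0.99
            assert (trace.flows >= -1e-15).all()
            # flows are consistent with occupancy differences
            assert np.allclose(
                trace.flows.sum(axis=1), trace.occupancy[1:], atol=1e-12
            )


class TestAccumulate:
    def test_one_person_year(self):
        trace = run_cohort(IDENTITY, 12)
        valuation = StateValuation(monthly_cost=(0, 0, 0), utility=(1.0, 1.0, 0.0))
        with pytest.warns(UserWarning, match="convergence"):  # nobody ever dies
            out = accumulate(trace, valuation, NO_DISCOUNT, half_cycle=False)
        assert out.qaly_total == pytest.approx(1.0, abs=1e-12)

    def test_zero_discount_equals_undiscounted(self):
        trace = run_cohort(LP_MATRIX, 600)
        out = accumulate(trace, SIMPLE_VALUATION, NO_DISCOUNT)
        assert out.cost_total == pytest.approx(out.undiscounted_cost_total, rel=1e-12)
        assert out.qaly_total == pytest.approx(out.undiscounted_qaly_total, rel=1e-12)

    def test_discount_monotonicity(self):
        trace = run_cohort(LP_MATRIX, 600)
        totals = [
            accumulate(trace, SIMPLE_VALUATION, DiscountSpec(rate))
            for rate in (0.0, 0.03, 0.06, 0.10)
        ]
        costs = [t.cost_total for t in totals]
        qalys = [t.qaly_total for t in totals]
        assert costs == sorted(costs, reverse=True)
        assert qalys == sorted(qalys, reverse=True)

    def test_half_cycle_bracket(self):
        trace = run_cohort(LP_MATRIX, 600)
        corrected = accumulate(trace, SIMPLE_VALUATION, half_cycle=True)
        start = accumulate(trace, SIMPLE_VALUATION, half_cycle=False)
        # cycle-end-weighted sum, computed directly from the trace
        disc = DiscountSpec().factors(600)
        util = np.array(SIMPLE_VALUATION.utility)
        end_qaly = ((trace.occupancy[1:] * disc[1:, None]) @ util).sum() / 12.0
        lo, hi = sorted((start.qaly_total, end_qaly))
        assert lo <= corrected.qaly_total <= hi

    def test_totals_match_decomposition(self):
        trace = run_cohort(LP_MATRIX, 600)
        valuation = StateValuation(
            monthly_cost=(1000.0, 500.0, 0.0),
            utility=(0.8, 0.6, 0.0),
            death_transition_cost=5000.0,
            entry_cost=600.0,
        )
        out = accumulate(trace, valuation)
        assert out.cost_total == pytest.approx(sum(out.cost_by_state.values()), abs=1e-8)
        assert out.qaly_total == pytest.approx(sum(out.qaly_by_state.values()), abs=1e-8)

    def test_death_transition_cost_charged_once_per_person(self):
        # undiscounted: everyone dies exactly once, so the palliative total
        # equals the per-event cost
        trace = run_cohort(LP_MATRIX, 600)
        valuation = StateValuation(
            monthly_cost=(0, 0, 0), utility=(0, 0, 0), death_transition_cost=11266.07
        )
        out = accumulate(trace, valuation, NO_DISCOUNT)
        assert out.undiscounted_cost_total == pytest.approx(11266.07, rel=1e-4)

    def test_short_horizon_warns(self):
        trace = run_cohort(LP_MATRIX, 5)
        with pytest.warns(UserWarning, match="convergence"):
            accumulate(trace, SIMPLE_VALUATION)

    def test_utility_validation(self):
        with pytest.raises(ValueError, match="utilities"):
            StateValuation(monthly_cost=(0, 0, 0), utility=(1.2, 0.5, 0.0))
        with pytest.raises(ValueError, match="Death utility"):
            StateValuation(monthly_cost=(0, 0, 0), utility=(0.8, 0.5, 0.1))


def _outcome(cost, qaly):
    return ArmOutcome(
        cost_total=cost, qaly_total=qaly, cost_by_state={}, qaly_by_state={},
        undiscounted_cost_total=cost, undiscounted_qaly_total=qaly,
    )


class TestCompare:
    def test_identical_arms(self):
        a = _outcome(1000.0, 1.0)
        result = compare(a, a, wtp=100_000)
        assert result.delta_cost == 0.0
        assert result.delta_qaly == 0.0
        assert result.nmb == 0.0
        assert result.icer is None

    def test_published_increments_reproduce_icer(self):
        result = compare(_outcome(241_278.18, 0.6379), _outcome(0.0, 0.0))
        assert result.icer == pytest.approx(378_251.44, rel=1e-3)
        assert result.dominance is None

    def test_dominance_flag(self):
        cheaper_better = compare(_outcome(500.0, 2.0), _outcome(1000.0, 1.0))
        assert cheaper_better.dominance == "intervention"
        assert cheaper_better.icer is None
        worse = compare(_outcome(1000.0, 1.0), _outcome(500.0, 2.0))
        assert worse.dominance == "comparator"

    def test_nmb_definition(self):
        result = compare(_outcome(150_000.0, 1.5), _outcome(50_000.0, 1.0), wtp=100_000)
        assert result.nmb == pytest.approx(100_000 * 0.5 - 100_000.0)

    def test_icer_invariant_to_shared_entry_cost(self):
        trace = run_cohort(LP_MATRIX, 600)
        trace_b = run_cohort(TransitionMatrix.from_probs(0.127, 0.059, 0.092), 600)
        base_vals = dict(monthly_cost=(1000.0, 500.0, 0.0), utility=(0.8, 0.6, 0.0))
        for entry in (0.0, 666.40, 5000.0):
            a = accumulate(trace, StateValuation(**base_vals, entry_cost=entry))
            b = accumulate(trace_b, StateValuation(**base_vals, entry_cost=entry))
            result = compare(a, b)
            if entry == 0.0:
                reference = result.icer
            else:
                assert result.icer == pytest.approx(reference, rel=1e-12)
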