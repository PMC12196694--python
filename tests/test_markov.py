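"""Cohort engine: cycle arithmetic, accrual convention, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hivcea import (
    CostSchedule,
    ModelConfig,
    StageVector,
    TransitionSchedule,
    UtilitySchedule,
    advance,
    microsim_oracle,
    run_cohort,
    summarize,
)
from hivcea.markov import CohortTrace

from conftest import random_row_stochastic


class TestStageVector:
    def test_renormalizes_printed_rounding(self):
        v = StageVector(np.array([0.38, 0.36, 0.20, 0.07]))  # sums to 1.01
        assert v.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert v.p[0] == pytest.approx(0.38 / 1.01)

    def test_rejects_negative_and_overlarge_deviation(self):
        with pytest.raises(ValueError):
            StageVector(np.array([-0.1, 0.5, 0.3, 0.3]))
        with pytest.raises(ValueError):
            StageVector(np.array([0.5, 0.5, 0.5, 0.5]))  # sum 2.0

    def test_warns_on_moderate_deviation(self):
        with pytest.warns(UserWarning, match="renormalized"):
            StageVector(np.array([0.40, 0.25, 0.20, 0.18]))  # sum 1.03


class TestTransitionSchedule:
    def test_carry_forward_returns_last_estimated_matrix(self, table2):
        assert table2.last_estimated_year == 3
        for year in (4, 5, 17):
            np.testing.assert_array_equal(table2.matrix_for(year), table2.matrix_for(3))

    def test_rows_stochastic_after_load(self, table2):
        for mat in table2.matrices.values():
            np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_years_must_be_contiguous_from_one(self):
        eye = np.eye(4)
        with pytest.raises(ValueError, match="contiguous"):
            TransitionSchedule({2: eye})


class TestAdvance:
    def test_worst_stage_through_year1_matrix(self, table2):
        # printed row (0.38, 0.36, 0.20, 0.07) sums to 1.01; engine divides by it
        out = advance(StageVector(np.eye(4)[0]), table2.matrix_for(1))
        np.testing.assert_allclose(
            out.p, [0.38 / 1.01, 0.36 / 1.01, 0.20 / 1.01, 0.07 / 1.01], atol=1e-12
        )

    def test_identity_keeps_state(self):
        out = advance(StageVector(np.eye(4)[3]), np.eye(4))
        np.testing.assert_array_equal(out.p, [0, 0, 0, 1])

    def test_baseline_one_cycle_best_stage_share(self, table1, table2):
        baseline, _, _ = table1
        out = advance(baseline, table2.matrix_for(1))
        assert out.p[3] == pytest.approx(0.388, abs=0.001)

    def test_rejects_bad_matrices(self):
        state = StageVector(np.full(4, 0.25))
        with pytest.raises(ValueError):
            advance(state, np.eye(3))
        with pytest.raises(ValueError):
            advance(state, -np.eye(4))
        with pytest.raises(ValueError):
            advance(state, np.full((4, 4), 0.5))  # rows sum to 2


class TestRunCohort:
    def test_absorbing_state_closed_form(self, identity_schedule):
        """Single absorbing stage, no discounting: plain sums."""
        costs = CostSchedule([100.0] * 4, [10.0] * 4)
        utils = UtilitySchedule([0.67, 0.70, 0.71, 0.73])
        cfg = ModelConfig(discount_rate_costs=0.0, discount_rate_qalys=0.0)
        trace = run_cohort(
            StageVector(np.eye(4)[3]), identity_schedule, costs, utils, cfg
        )
        res = summarize(trace, cfg)
        assert res.total_qalys == pytest.approx(6 * 0.73)
        assert res.total_cost == pytest.approx(100 + 5 * 10)

    def test_trace_shape_and_occupancy(self, base_inputs):
        trace = run_cohort(
            base_inputs.baseline,
            base_inputs.transitions,
            base_inputs.costs,
            base_inputs.utilities,
            base_inputs.config,
        )
        assert trace.occupancy.shape == (6, 4)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(
            trace.occupancy[0], base_inputs.baseline.as_array()
        )
        assert np.all(trace.cost_accruals >= 0)
        # discounted per-point QALYs can never beat the best utility
        t = np.arange(6)
        assert np.all(trace.qaly_accruals <= 0.73 / 1.05**t + 1e-12)

    def test_qaly_total_bounded_by_best_utility(self, base_inputs):
        trace = run_cohort(
            base_inputs.baseline,
            base_inputs.transitions,
            base_inputs.costs,
            base_inputs.utilities,
            base_inputs.config,
        )
        assert trace.qaly_accruals.sum() <= 6 * 0.73

    def test_discount_monotonicity(self, base_inputs):
        totals = []
        for r in (0.0, 0.03, 0.05, 0.10):
            cfg = ModelConfig(discount_rate_costs=r, discount_rate_qalys=r)
            trace = run_cohort(
                base_inputs.baseline,
                base_inputs.transitions,
                base_inputs.costs,
                base_inputs.utilities,
                cfg,
            )
            res = summarize(trace, cfg)
            totals.append((res.total_cost, res.total_qalys))
        costs_seq = [c for c, _ in totals]
        qalys_seq = [q for _, q in totals]
        assert costs_seq == sorted(costs_seq, reverse=True)
        assert qalys_seq == sorted(qalys_seq, reverse=True)


class TestSummarize:
    def test_ratio_is_arithmetic_identity(self):
        trace = CohortTrace(
            occupancy=np.tile([1, 0, 0, 0], (2, 1)).astype(float),
            cost_accruals=np.array([100.0, 100.0]),
            qaly_accruals=np.array([0.5, 0.5]),
        )
        res = summarize(trace)
        assert res.total_cost == 200.0
        assert res.total_qalys == 1.0
        assert res.cost_per_qaly == 200.0
        assert res.below_wtp

    def test_zero_cost_schedule(self, base_inputs):
        zero = CostSchedule(np.zeros(4), np.zeros(4))
        trace = run_cohort(
            base_inputs.baseline,
            base_inputs.transitions,
            zero,
            base_inputs.utilities,
            base_inputs.config,
        )
        res = summarize(trace, base_inputs.config)
        assert res.total_cost == 0.0
        assert res.cost_per_qaly == 0.0
        assert res.below_wtp

    def test_zero_qalys_with_cost_is_undefined(self):
        trace = CohortTrace(
            occupancy=np.tile([1, 0, 0, 0], (2, 1)).astype(float),
            cost_accruals=np.array([1.0, 1.0]),
            qaly_accruals=np.zeros(2),
        )
        with pytest.raises(ZeroDivisionError):
            summarize(trace)


class TestMicrosimOracle:
    def test_single_absorbing_individual_matches_closed_form(self, identity_schedule):
        costs = CostSchedule([100.0] * 4, [10.0] * 4)
        utils = UtilitySchedule([0.67, 0.70, 0.71, 0.73])
        cfg = ModelConfig(discount_rate_costs=0.0, discount_rate_qalys=0.0)
        res = microsim_oracle(
            StageVector(np.eye(4)[3]),
            identity_schedule,
            costs,
            utils,
            cfg,
            n_individuals=1,
            seed=7,
        )
        assert res.total_qalys == pytest.approx(6 * 0.73)
        assert res.total_cost == pytest.approx(150.0)

    def test_seed_to_seed_variation_is_small(self, base_inputs):
        a = microsim_oracle(
            base_inputs.baseline,
            base_inputs.transitions,
            base_inputs.costs,
            base_inputs.utilities,
            base_inputs.config,
            n_individuals=200_000,
            seed=11,
        )
        b = microsim_oracle(
            base_inputs.baseline,
            base_inputs.transitions,
            base_inputs.costs,
            base_inputs.utilities,
            base_inputs.config,
            n_individuals=200_000,
            seed=12,
        )
        assert abs(a.total_cost - b.total_cost) / a.total_cost < 0.005
        assert abs(a.total_qalys - b.total_qalys) / a.total_qalys < 0.005


class TestOccupancyConservationProperty:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), horizon=st.integers(1, 8))
    def test_random_schedules_conserve_probability(self, seed, horizon):
        rng = np.random.default_rng(seed)
        sched = TransitionSchedule(
            {t: random_row_stochastic(rng) for t in range(1, horizon + 1)}
        )
        p = rng.random(4) + 1e-3
        baseline = StageVector(p / p.sum())
        costs = CostSchedule(rng.random(4) * 1000, rng.random(4) * 1000)
        utils = UtilitySchedule(rng.random(4))
        cfg = ModelConfig(horizon_years=horizon)
        trace = run_cohort(baseline, sched, costs, utils, cfg)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(trace.cost_accruals >= 0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_zero_discount_reproduces_plain_sums(self, seed):
        rng = np.random.default_rng(seed)
        sched = TransitionSchedule({1: random_row_stochastic(rng)})
        p = rng.random(4) + 1e-3
        baseline = StageVector(p / p.sum())
        init, incr = rng.random(4) * 100, rng.random(4) * 100
        utils_arr = rng.random(4)
        cfg = ModelConfig(
            horizon_years=3, discount_rate_costs=0.0, discount_rate_qalys=0.0
        )
        trace = run_cohort(
            baseline, sched, CostSchedule(init, incr), UtilitySchedule(utils_arr), cfg
        )
        occ = trace.occupancy
        expected_cost = occ[0] @ init + sum(occ[t] @ incr for t in range(1, 4))
        expected_qalys = sum(occ[t] @ utils_arr for t in range(4))
        assert trace.cost_accruals.sum() == pytest.approx(expected_cost)
        assert trace.qaly_accruals.sum() == pytest.approx(expected_qalys)
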