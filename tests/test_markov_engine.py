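"""Markov engine: transition matrices, cohort traces, half-cycle accrual,
discounting, and agreement with an independent microsimulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbscea import markov_engine as me
from nbscea.parameters import CourseCurve

from _microsim import max_z_vs_trace, microsimulate

NS_DEAD = me.state_set_for(())
ONE_SEQ = me.state_set_for(("ND",))
TWO_SEQ = me.state_set_for(("ND", "RD"))


def geometric_toy(p_death=0.5, cycles=2):
    """Constant-death toy: alive occupancies 1, 0.5, 0.25 ..."""
    mats = np.stack([me.build_transition_matrix(NS_DEAD, p_death, {}, 0.0)] * cycles)
    return me.run_cohort_trace(mats, 1.0, NS_DEAD)


class TestTransitionMatrix:
    def test_zero_risk_is_identity(self):
        m = me.build_transition_matrix(ONE_SEQ, 0.0, {"ND": 0.0}, 0.0)
        assert np.array_equal(m, np.eye(3))

    def test_pure_death_row(self):
        m = me.build_transition_matrix(NS_DEAD, 0.5, {}, 0.0)
        assert m[0].tolist() == [0.5, 0.5]

    def test_death_then_onset_composition(self):
        # death 0.2 first, onset 0.1 among survivors: Dead .2, ND .08, stay .72
        m = me.build_transition_matrix(ONE_SEQ, 0.2, {"ND": 0.1}, 0.0)
        assert m[0, ONE_SEQ.index("Dead")] == pytest.approx(0.2)
        assert m[0, ONE_SEQ.index("ND")] == pytest.approx(0.08)
        assert m[0, 0] == pytest.approx(0.72)

    def test_background_combines_as_independent_hazard(self):
        m = me.build_transition_matrix(NS_DEAD, 0.2, {}, 0.1)
        assert m[0, 1] == pytest.approx(1 - 0.8 * 0.9)

    def test_sequela_rows_share_mortality_and_stay(self):
        m = me.build_transition_matrix(TWO_SEQ, 0.2, {"ND": 0.1, "RD": 0.05}, 0.0)
        for seq in ("ND", "RD"):
            i = TWO_SEQ.index(seq)
            assert m[i, i] == pytest.approx(0.8)
            assert m[i, TWO_SEQ.index("Dead")] == pytest.approx(0.2)
        # no inter-sequela arrows
        assert m[TWO_SEQ.index("ND"), TWO_SEQ.index("RD")] == 0.0

    def test_overflowing_onsets_rejected(self):
        with pytest.raises(ValueError):
            me.build_transition_matrix(TWO_SEQ, 0.0, {"ND": 0.7, "RD": 0.6}, 0.0)

    @given(
        death=st.floats(0, 1), bg=st.floats(0, 1),
        o1=st.floats(0, 0.5), o2=st.floats(0, 0.5),
    )
    def test_rows_are_stochastic(self, death, bg, o1, o2):
        m = me.build_transition_matrix(TWO_SEQ, death, {"ND": o1, "RD": o2}, bg)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert m.min() >= 0.0


class TestCohortTrace:
    def test_identity_matrices_freeze_occupancy(self):
        mats = np.stack([np.eye(2)] * 5)
        trace = me.run_cohort_trace(mats, np.array([0.7, 0.3]), NS_DEAD)
        assert np.all(trace.occupancy == [0.7, 0.3])

    def test_geometric_decay(self):
        trace = geometric_toy()
        assert trace.state_column("NS").tolist() == [1.0, 0.5, 0.25]

    def test_non_stochastic_matrix_rejected(self):
        mats = np.stack([np.array([[0.5, 0.4], [0.0, 1.0]])])
        with pytest.raises(ValueError, match="non-stochastic"):
            me.run_cohort_trace(mats, 1.0, NS_DEAD)

    @given(
        death=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        onset=st.lists(st.floats(0, 1), min_size=4, max_size=4),
        mass=st.floats(0.1, 1e6),
    )
    def test_mass_conserved_every_cycle(self, death, onset, mass):
        curve = CourseCurve(p_death=np.array(death), p_onset={"ND": np.array(onset)})
        mats = me.build_matrices(ONE_SEQ, curve, np.zeros(4), 4)
        trace = me.run_cohort_trace(mats, mass, ONE_SEQ)
        assert np.allclose(trace.occupancy.sum(axis=1), mass, rtol=1e-9)


class TestHalfCycleCorrection:
    def test_trapezoid_on_geometric_toy(self):
        # alive (1, .5, .25): person-years 0.75 + 0.375 = 1.125
        trace = geometric_toy()
        assert me.half_cycle_corrected_time(trace)[0] == pytest.approx(1.125)

    def test_no_deaths_gives_full_horizon(self):
        mats = np.stack([np.eye(2)] * 7)
        trace = me.run_cohort_trace(mats, 1.0, NS_DEAD)
        assert me.half_cycle_corrected_time(trace)[0] == pytest.approx(7.0)

    def test_all_dead_at_start_gives_zero(self):
        mats = np.stack([np.eye(2)] * 3)
        trace = me.run_cohort_trace(mats, np.array([0.0, 1.0]), NS_DEAD)
        assert me.half_cycle_corrected_time(trace)[0] == 0.0

    @given(death=st.lists(st.floats(0, 1), min_size=5, max_size=5))
    def test_corrected_time_between_start_and_end_counting(self, death):
        curve = CourseCurve(p_death=np.array(death), p_onset={})
        mats = me.build_matrices(NS_DEAD, curve, np.zeros(5), 5)
        trace = me.run_cohort_trace(mats, 1.0, NS_DEAD)
        alive = trace.state_column("NS")
        corrected = me.half_cycle_corrected_time(trace)[0]
        assert alive[1:].sum() - 1e-12 <= corrected <= alive[:-1].sum() + 1e-12


class TestDiscounting:
    def test_zero_rate_is_unity(self):
        assert me.discount_factor(0.0, 17) == 1.0

    def test_mid_cycle_factors(self):
        assert me.discount_factor(0.03, 0) == pytest.approx(0.985329, abs=5e-7)
        assert me.discount_factor(0.03, 1) == pytest.approx(0.956630, abs=5e-7)

    def test_end_cycle_switch(self):
        assert me.discount_factor(0.03, 0, timing="end") == pytest.approx(1 / 1.03)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            me.discount_factor(-0.01, 0)


class TestAccumulateOutcomes:
    def test_undiscounted_full_life_qaly(self):
        mats = np.stack([np.eye(2)] * 82)
        trace = me.run_cohort_trace(mats, 1.0, NS_DEAD)
        res = me.accumulate_outcomes(trace, np.zeros(2), np.array([1.0, 0.0]), 0.0)
        assert res.qaly == pytest.approx(82.0)
        assert res.cost == 0.0

    def test_zero_rate_cost_equals_person_years_times_annual_cost(self):
        trace = geometric_toy(p_death=0.3, cycles=6)
        res = me.accumulate_outcomes(trace, np.array([123.0, 0.0]), np.array([1.0, 0.0]), 0.0)
        py = me.half_cycle_corrected_time(trace)[0]
        assert res.cost == pytest.approx(py * 123.0, rel=1e-12)

    def test_discounted_toy_hand_computation(self):
        # alive (1, .5, .25), utility 1, 3%: 0.75/1.03^0.5 + 0.375/1.03^1.5
        trace = geometric_toy()
        res = me.accumulate_outcomes(trace, np.zeros(2), np.array([1.0, 0.0]), 0.03)
        assert res.qaly == pytest.approx(0.75 / 1.03 ** 0.5 + 0.375 / 1.03 ** 1.5, rel=1e-12)
        assert res.qaly == pytest.approx(1.098, abs=5e-4)

    def test_zero_rate_equals_undiscounted_sums_exactly(self):
        trace = geometric_toy(p_death=0.2, cycles=10)
        costs, utils = np.array([50.0, 0.0]), np.array([0.9, 0.0])
        res = me.accumulate_outcomes(trace, costs, utils, 0.0)
        time = me.per_cycle_state_time(trace)
        assert res.cost == (time * costs).sum()
        assert res.qaly == (time * utils).sum()

    def test_qalys_strictly_decrease_with_rate(self):
        trace = geometric_toy(p_death=0.1, cycles=20)
        utils = np.array([1.0, 0.0])
        q = [me.accumulate_outcomes(trace, np.zeros(2), utils, r).qaly
             for r in (0.0, 0.01, 0.03, 0.05, 0.10)]
        assert all(a > b for a, b in zip(q, q[1:]))

    def test_age_dependent_cost_matrix(self):
        mats = np.stack([np.eye(2)] * 4)
        trace = me.run_cohort_trace(mats, 1.0, NS_DEAD)
        costs = np.zeros((4, 2))
        costs[2:, 0] = 10.0  # costs start at age 2
        res = me.accumulate_outcomes(trace, costs, np.array([1.0, 0.0]), 0.0)
        assert res.cost == pytest.approx(20.0)


class TestMicrosimulationAgreement:
    def test_cohort_trace_matches_individual_sampling(self):
        curve = CourseCurve(
            p_death=np.where(np.arange(30) < 2, 0.1, 0.02),
            p_onset={"ND": np.where(np.arange(30) < 5, 0.15, 0.0)},
        )
        mats = me.build_matrices(ONE_SEQ, curve, np.full(30, 0.005), 30)
        trace = me.run_cohort_trace(mats, 1.0, ONE_SEQ)
        counts = microsimulate(mats, n=20_000, seed=7)
        assert max_z_vs_trace(trace.occupancy, counts, 20_000) <= 3.0
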