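"""W'-balance bookkeeping and the Skiba exhaustion-power solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiitsim import ModelDomainError, SessionPlan
from hiitsim.skiba import (
    deplete_step,
    recover_step,
    simulate_wbal,
    solve_exhaustion_power,
    solve_exhaustion_power_bisect,
)

CP_TT, WPRIME_TT = 304.0, 21500.0


class TestSteps:
    def test_depletion_is_linear_in_excess_power(self):
        assert deplete_step(21500, 431, CP_TT, 10) == pytest.approx(20230.0)

    def test_power_at_cp_leaves_balance_unchanged(self):
        assert deplete_step(12345.0, CP_TT, CP_TT, 999) == 12345.0

    def test_depletion_may_overshoot_below_zero(self):
        assert deplete_step(1000, 404, CP_TT, 20) == pytest.approx(-1000.0)

    def test_deplete_below_cp_is_a_contract_error(self):
        with pytest.raises(ModelDomainError):
            deplete_step(20000, 200, CP_TT, 10)

    def test_recovery_refills_the_deficit_exponentially(self):
        # deficit 11500 J decays by exp((191-304)*60/21500)
        got = recover_step(10000, WPRIME_TT, 191, CP_TT, 60)
        assert got == pytest.approx(13110.355, abs=1e-3)

    def test_full_reserve_is_a_fixed_point(self):
        assert recover_step(WPRIME_TT, WPRIME_TT, 100, CP_TT, 1e6) == WPRIME_TT

    def test_recovery_approaches_full_reserve_in_the_limit(self):
        got = recover_step(5000, WPRIME_TT, CP_TT - 1, CP_TT, 1e9)
        assert got == pytest.approx(WPRIME_TT, rel=1e-9)

    def test_recover_at_or_above_cp_is_a_contract_error(self):
        with pytest.raises(ModelDomainError):
            recover_step(10000, WPRIME_TT, CP_TT, CP_TT, 10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        frac=st.floats(0, 1),
        power=st.floats(0, CP_TT - 1e-6),
        dt=st.floats(1e-3, 1e4),
    )
    def test_recovery_is_bounded_and_monotone(self, frac, power, dt):
        """The balance never exceeds W' and grows with recovery time."""
        wbal = frac * WPRIME_TT
        once = recover_step(wbal, WPRIME_TT, power, CP_TT, dt)
        twice = recover_step(wbal, WPRIME_TT, power, CP_TT, 2 * dt)
        assert wbal - 1e-9 <= once <= WPRIME_TT
        assert twice >= once - 1e-9


class TestSimulate:
    def test_single_bout_exhausts_exactly_at_the_end(self):
        work = 100.0  # W'/work is exact in binary, so the final sample is exactly 0
        plan = SessionPlan(1, work, 0, 0, work_power=CP_TT + WPRIME_TT / work)
        trajectory = simulate_wbal(plan, CP_TT, WPRIME_TT)
        assert trajectory.exhaustion_time == pytest.approx(work, abs=1e-9)
        assert trajectory.wbal[0] == WPRIME_TT
        assert trajectory.wbal[-1] == pytest.approx(0.0, abs=1e-9)

    def test_solved_session_ends_with_zero_balance(self):
        plan = SessionPlan(2, 60, 120, 150)
        p_star = solve_exhaustion_power(plan, CP_TT, WPRIME_TT)
        trajectory = simulate_wbal(plan.with_work_power(p_star), CP_TT, WPRIME_TT)
        assert abs(trajectory.wbal[-1]) < 1.0
        # rounding of the exactly-solved power may place the zero crossing a
        # hair before or after the final sample
        if trajectory.exhausted:
            assert trajectory.exhaustion_time == pytest.approx(plan.total_duration, abs=0.5)
        else:
            assert trajectory.times[-1] == plan.total_duration

    def test_near_cp_work_with_long_rest_never_exhausts(self):
        plan = SessionPlan(3, 30, 1800, 150, work_power=CP_TT + 0.5)
        trajectory = simulate_wbal(plan, CP_TT, WPRIME_TT)
        assert not trajectory.exhausted
        assert trajectory.wbal[-1] > 0.99 * WPRIME_TT
        assert np.all(trajectory.wbal <= WPRIME_TT)

    def test_overdriven_session_exhausts_mid_session(self):
        plan = SessionPlan(4, 60, 60, 150)
        p_star = solve_exhaustion_power(plan, CP_TT, WPRIME_TT)
        trajectory = simulate_wbal(plan.with_work_power(p_star + 50), CP_TT, WPRIME_TT)
        assert trajectory.exhausted
        assert trajectory.exhaustion_time < plan.total_duration
        assert trajectory.wbal[-1] == 0.0

    def test_rest_power_at_or_above_cp_is_rejected(self):
        plan = SessionPlan(2, 60, 60, CP_TT + 1, work_power=400)
        with pytest.raises(ModelDomainError, match="recovery undefined above CP"):
            simulate_wbal(plan, CP_TT, WPRIME_TT)


class TestSolver:
    def test_single_bout_reduces_to_the_continuous_cp_model(self):
        plan = SessionPlan(1, 180, 60, 150)
        assert solve_exhaustion_power(plan, CP_TT, WPRIME_TT) == pytest.approx(
            CP_TT + WPRIME_TT / 180
        )

    def test_reference_short_interval_session(self):
        """2 x 15 s with 5 min recovery at 191 W demands ~1492 W."""
        plan = SessionPlan(2, 15, 300, 191)
        lam = math.exp((191 - CP_TT) * 300 / WPRIME_TT)
        expected = CP_TT + WPRIME_TT * (1 - lam) / (15 * (1 - lam**2))
        got = solve_exhaustion_power(plan, CP_TT, WPRIME_TT)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1491.86, abs=0.01)

    def test_zero_rest_limit_is_one_continuous_effort(self):
        plan = SessionPlan(4, 60, 0, 150)
        assert solve_exhaustion_power(plan, CP_TT, WPRIME_TT) == pytest.approx(
            CP_TT + WPRIME_TT / (4 * 60)
        )
        tiny = SessionPlan(4, 60, 1e-9, 150)
        assert solve_exhaustion_power(tiny, CP_TT, WPRIME_TT) == pytest.approx(
            CP_TT + WPRIME_TT / 240, rel=1e-9
        )

    def test_monotone_in_session_parameters(self):
        """More rest raises, more reps or longer bouts lower, the required power."""
        base = dict(n_reps=4, work_duration=60, rest_duration=120, rest_power=150)
        p0 = solve_exhaustion_power(SessionPlan(**base), CP_TT, WPRIME_TT)
        more_rest = solve_exhaustion_power(
            SessionPlan(**{**base, "rest_duration": 240}), CP_TT, WPRIME_TT
        )
        more_reps = solve_exhaustion_power(
            SessionPlan(**{**base, "n_reps": 8}), CP_TT, WPRIME_TT
        )
        longer_work = solve_exhaustion_power(
            SessionPlan(**{**base, "work_duration": 120}), CP_TT, WPRIME_TT
        )
        assert more_rest > p0
        assert more_reps < p0
        assert longer_work < p0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 8),
        work=st.integers(10, 240),
        rest=st.integers(5, 240),
        cp=st.floats(200, 320),
        wprime=st.floats(15e3, 33e3),
        rest_frac=st.floats(0.1, 0.9),
    )
    def test_closed_form_agrees_with_simulation_bisection(
        self, n, work, rest, cp, wprime, rest_frac
    ):
        """Two independent routes to the exhaustion power coincide."""
        plan = SessionPlan(n, work, rest, rest_frac * cp)
        closed = solve_exhaustion_power(plan, cp, wprime)
        bisected = solve_exhaustion_power_bisect(plan, cp, wprime, tol=1e-3, dt=1.0)
        assert closed == pytest.approx(bisected, abs=0.01)


def test_plan_duration_conventions():
    plan = SessionPlan(3, 45, 90, 100)
    assert plan.total_duration == 3 * 45 + 2 * 90
    assert plan.total_work_time == 135
    with pytest.raises(ValueError):
        SessionPlan(0, 45, 90, 100)
    with pytest.raises(ValueError):
        SessionPlan(2, -5, 90, 100)
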