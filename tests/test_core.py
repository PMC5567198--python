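"""Mean model: closed forms against numerical oracles, conservation laws."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from milksession.core import (
    MilkingSchedule,
    active_fraction_integral,
    alveolar_state,
    expected_yields,
    extraction_series,
    mean_active_fraction,
    secreted_between_sessions,
)
from milksession.params import MeanParams


def ode_oracle(t, lambda_a, lambda_r):
    """High-accuracy numerical integration of the three-class kinetics."""

    def rhs(_, y):
        ni, na, nr = y
        return [-lambda_a * ni, lambda_a * ni - lambda_r * na, lambda_r * na]

    sol = solve_ivp(rhs, (0.0, t), [1.0, 0.0, 0.0], rtol=1e-11, atol=1e-13,
                    dense_output=True)
    return sol.y[:, -1]


class TestAlveolarState:
    def test_initial_condition(self):
        st = alveolar_state(0.0, 0.0064, 4.5e-5)
        assert (st.n_inactive, st.n_active, st.n_retired) == (1.0, 0.0, 0.0)

    def test_no_inactivation_collapses_to_saturating_exponential(self):
        st = alveolar_state(100.0, 0.0064, 0.0)
        assert st.n_active == pytest.approx(1.0 - np.exp(-0.64), abs=1e-14)

    @pytest.mark.parametrize(
        "t,la,lr",
        [
            (500.0, 0.0064, 4.5e-5),
            (100.0, 0.0064, 4.5e-5),
            (5000.0, 0.0064, 4.5e-5),
            (200.0, 0.01, 0.009),
            (300.0, 1e-3, 1e-3 * (1 + 5e-11)),  # near-degenerate
            (300.0, 1e-3, 1e-3 * (1 - 1e-13)),  # inside the analytic-limit band
        ],
    )
    def test_matches_ode_oracle(self, t, la, lr):
        ni, na, nr = ode_oracle(t, la, lr)
        st = alveolar_state(t, la, lr)
        assert st.n_inactive == pytest.approx(ni, abs=1e-8)
        assert st.n_active == pytest.approx(na, abs=1e-8)
        assert st.n_retired == pytest.approx(nr, abs=1e-8)

    def test_proportions_sum_to_one_and_monotone(self):
        ts = np.linspace(0, 8000, 60)
        states = [alveolar_state(t, 0.0064, 4.5e-5) for t in ts]
        for st in states:
            assert st.n_inactive + st.n_active + st.n_retired == pytest.approx(1.0, abs=1e-12)
        ni = [s.n_inactive for s in states]
        nr = [s.n_retired for s in states]
        assert all(a >= b - 1e-15 for a, b in zip(ni, ni[1:]))
        assert all(a <= b + 1e-15 for a, b in zip(nr, nr[1:]))

    def test_late_lactation_decline_emerges(self):
        st = alveolar_state(5e6, 0.0064, 4.5e-5)
        assert st.n_retired == pytest.approx(1.0, abs=1e-6)
        y = secreted_between_sessions(
            5e6, 5e6 + 14,
            MeanParams(delta=70.0, lambda_a=0.0064, lambda_r=4.5e-5, pi=0.0),
            1.41,
        )
        assert y < 1e-6

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            alveolar_state(-1.0, 0.0064, 4.5e-5)
        with pytest.raises(ValueError):
            alveolar_state(1.0, -0.0064, 4.5e-5)


class TestMeanActiveFraction:
    @pytest.mark.parametrize("t0,t1", [(100.0, 114.0), (0.0, 70.98), (3000.0, 3010.0)])
    def test_matches_quadrature(self, t0, t1):
        la, lr = 0.0064, 4.5e-5
        num, _ = quad(
            lambda x: (la / (la - lr)) * (np.exp(-lr * x) - np.exp(-la * x)),
            t0, t1, epsabs=1e-13, epsrel=1e-13,
        )
        assert mean_active_fraction(t0, t1, la, lr) == pytest.approx(
            num / (t1 - t0), abs=1e-10
        )
        assert 0.0 <= mean_active_fraction(t0, t1, la, lr) <= 1.0

    def test_increases_over_time_without_inactivation(self):
        vals = [mean_active_fraction(t, t + 10, 0.0064, 0.0) for t in (0, 50, 200, 800)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            mean_active_fraction(10.0, 10.0, 0.0064, 4.5e-5)


class TestSecretion:
    def test_linear_in_pl(self, simple_params):
        y1 = secreted_between_sessions(100, 114, simple_params, 1.41)
        y2 = secreted_between_sessions(100, 114, simple_params, 2.82)
        assert y2 == pytest.approx(2 * y1, rel=1e-14)
        assert secreted_between_sessions(100, 114, simple_params, 0.0) == 0.0

    def test_first_interval_matches_quadrature(self, simple_params):
        la, lr = simple_params.lambda_a, simple_params.lambda_r
        num, _ = quad(
            lambda x: (la / (la - lr)) * (np.exp(-lr * x) - np.exp(-la * x)),
            0.0, 70.98, epsabs=1e-12,
        )
        y = secreted_between_sessions(0.0, 70.98, simple_params, 1.41)
        assert y == pytest.approx(1.41 * num, abs=1e-9)


class TestExtractionSeries:
    def test_milk_conservation(self, nominal_schedule, ref_params):
        ys = extraction_series(nominal_schedule, ref_params)
        prev_r = 0.0
        for s in ys:
            assert s.y_extracted + s.y_residual == pytest.approx(
                s.y_produced + prev_r, abs=1e-12
            )
            assert min(s.y_extracted, s.y_residual, s.y_produced) >= 0.0
            prev_r = s.y_residual

    def test_no_retention_means_full_extraction(self, nominal_schedule, ref_params):
        p = ref_params.with_(pi=0.0, pi_overrides={})
        for s in extraction_series(nominal_schedule, p):
            assert s.y_residual == 0.0
            assert s.y_extracted == pytest.approx(s.y_produced, abs=1e-14)

    def test_residual_matches_unrolled_sum(self, short_schedule, simple_params):
        """Y_R(k) = sum_j pi^{k-j+1} Y_P(j) for constant pi (recursion unrolled)."""
        y_p, y_r, _ = expected_yields(short_schedule, simple_params)
        pi = simple_params.pi
        for k in range(len(y_p)):
            unrolled = sum(pi ** (k - j + 1) * y_p[j] for j in range(k + 1))
            assert y_r[k] == pytest.approx(unrolled, rel=1e-12)

    def test_extraction_rule_hand_arithmetic(self, short_schedule, simple_params):
        """Each session extracts (1 - pi) of produced-plus-carryover milk."""
        y_p, y_r, y_e = expected_yields(short_schedule, simple_params)
        avail = y_p[0]
        assert y_e[0] == pytest.approx(0.96 * avail, rel=1e-12)
        assert y_r[0] == pytest.approx(0.04 * avail, rel=1e-12)
        avail2 = y_p[1] + y_r[0]
        assert y_e[1] == pytest.approx(0.96 * avail2, rel=1e-12)

    def test_extraction_monotone_decreasing_in_pi(self, short_schedule, simple_params):
        """Raising retention lowers the first extraction and the running
        total (milk parked as carryover); steady-state per-session
        extraction itself converges back to production."""
        firsts, totals = [], []
        for pi in (0.0, 0.02, 0.05, 0.2):
            _, _, y_e = expected_yields(short_schedule, simple_params.with_(pi=pi))
            firsts.append(y_e[0])
            totals.append(y_e.sum())
        assert all(a > b for a, b in zip(firsts, firsts[1:]))
        assert all(a > b for a, b in zip(totals, totals[1:]))


class TestMilkingSchedule:
    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            MilkingSchedule([70.0, 70.0], ["M", "E"], 70.0)

    def test_from_hours_since_first(self):
        sch = MilkingSchedule.from_hours_since_first([0.0, 10.0, 24.0], ["M", "E", "M"], 71.0)
        assert sch.times[0] == 71.0
        assert sch.prev_times[0] == 0.0
        assert sch.intervals[0] == 71.0
        assert sch.intervals[1] == 10.0
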