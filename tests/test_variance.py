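"""Variance model: decomposition identity, independent oracles, timing term."""

import numpy as np
import pytest

from milksession.core import mean_active_fraction, n_active
from milksession.variance import (
    production_moments,
    propagate_moment_arrays,
    propagate_session_moments,
    timing_variance,
    variance_shares,
)


class TestProductionMoments:
    def test_full_beta_kills_proportion_variance(self):
        _, v_pl, _ = production_moments(100, 114, 1.41, 1.0, 0.54, 0.0064, 4.5e-5)
        assert v_pl == 0.0

    def test_zero_phi_kills_alveolar_variance(self):
        _, _, v_pa = production_moments(100, 114, 1.41, 0.9, 0.0, 0.0064, 4.5e-5)
        assert v_pa == 0.0

    def test_against_independent_scalar_formulas(self):
        """Term-by-term re-implementation with scalar arithmetic."""
        t0, t1, plmax, beta, phi, la, lr = 100.0, 114.0, 1.41, 0.94, 0.54, 0.0064, 4.5e-5
        dt = t1 - t0
        m = float(mean_active_fraction(t0, t1, la, lr))
        mean, v_pl, v_pa = production_moments(t0, t1, plmax, beta, phi, la, lr)
        assert mean == pytest.approx(plmax * beta * dt * m, abs=1e-12)
        assert v_pl == pytest.approx(plmax * dt * m * beta * (1 - beta), abs=1e-12)
        assert v_pa == pytest.approx(
            (plmax * beta) ** 2 * dt * phi * m * (1 - m), abs=1e-12
        )

    def test_rejects_invalid_beta(self):
        with pytest.raises(ValueError):
            production_moments(100, 114, 1.41, 0.0, 0.54, 0.0064, 4.5e-5)


class TestPropagation:
    def test_measurement_only_limit(self, short_schedule, simple_params, simple_var_params):
        """With pi = 0, phi = 0, beta = 1 only measurement error survives."""
        p = simple_params.with_(pi=0.0)
        vp = simple_var_params.with_(phi=0.0)
        a = propagate_moment_arrays(short_schedule, p, vp)
        expected = a["mean_produced"] ** 2 * vp.cv_measurement**2
        np.testing.assert_allclose(a["var_total"], expected, rtol=1e-12)

    def test_components_sum_to_total(self, nominal_schedule, ref_params, ref_var_params):
        for iu in (False, True):
            a = propagate_moment_arrays(nominal_schedule, ref_params, ref_var_params, iu)
            total = a["v_mes"] + a["v_ret"] + a["v_rec"] + a["v_pro"] + a["v_alv"] + a["v_tim"]
            np.testing.assert_allclose(a["var_total"], total, rtol=1e-10)
            assert all(np.all(a[c] >= 0) for c in ("v_mes", "v_ret", "v_rec", "v_pro", "v_alv", "v_tim"))

    def test_zero_retention_zeroes_retention_and_carryover(self, short_schedule, simple_params, simple_var_params):
        a = propagate_moment_arrays(short_schedule, simple_params.with_(pi=0.0), simple_var_params)
        assert np.all(a["v_ret"] == 0.0)
        assert np.all(a["v_rec"] == 0.0)

    def test_carryover_depends_on_previous_residual_variance(
        self, short_schedule, simple_params, simple_var_params
    ):
        a = propagate_moment_arrays(short_schedule, simple_params, simple_var_params)
        pi = simple_params.pi
        vr_prev = np.concatenate([[0.0], a["var_residual"][:-1]])
        np.testing.assert_allclose(a["v_rec"], (1 - pi) ** 2 * vr_prev, rtol=1e-12)

    def test_interval_uncertainty_strictly_increases_variance(
        self, nominal_schedule, ref_params, ref_var_params
    ):
        a0 = propagate_moment_arrays(nominal_schedule, ref_params, ref_var_params, False)
        a1 = propagate_moment_arrays(nominal_schedule, ref_params, ref_var_params, True)
        assert np.all(a1["var_total"] > a0["var_total"])

    def test_monte_carlo_oracle_short_chain(self, short_schedule, ref_var_params, simple_params):
        """Propagated Var(Y_M(k)) matches the generative draw (moment oracle)."""
        from milksession.simulate import SimConfig, _draw_chain

        cfg = SimConfig(mean_params=simple_params, var_params=ref_var_params, n_days=10)
        rng = np.random.default_rng(42)
        y_m, _, _, _ = _draw_chain(cfg, short_schedule, rng, 40000)
        a = propagate_moment_arrays(short_schedule, simple_params, ref_var_params)
        for k in (0, 1, 5, 10, 19):
            x = y_m[:, k]
            sv = x.var()
            kurt = np.mean((x - x.mean()) ** 4) / sv**2
            se = sv * np.sqrt((kurt - 1) / len(x))
            assert abs(sv - a["var_total"][k]) < 4 * se
            assert abs(x.mean() - a["mean_measured"][k]) < 4 * np.sqrt(sv / len(x))


class TestTimingVariance:
    def test_zero_interval_variance(self):
        assert timing_variance(200.0, 14.0, 1.41, 0.04, 0.0064, 4.5e-5, 0.0) == 0.0

    def test_full_retention_zeroes_it(self):
        assert timing_variance(200.0, 14.0, 1.41, 1.0, 0.0064, 4.5e-5, 0.25) == 0.0

    def test_matches_delta_method(self):
        """First-order variance of Y_P w.r.t. interval length by numeric
        differentiation of the secretion integral."""
        from milksession.core import active_fraction_integral

        t_prev, dt, pl, pi, la, lr, var_t = 200.0, 14.0, 1.41, 0.04, 0.0064, 4.5e-5, 0.25
        eps = 1e-5
        d = (
            active_fraction_integral(t_prev, t_prev + dt + eps, la, lr)
            - active_fraction_integral(t_prev, t_prev + dt - eps, la, lr)
        ) / (2 * eps)
        expected = (1 - pi) ** 2 * (pl * d) ** 2 * var_t
        got = timing_variance(t_prev, dt, pl, pi, la, lr, var_t)
        assert got == pytest.approx(expected, rel=1e-2)

    def test_sensitivity_is_activated_fraction_at_session_time(self):
        got = timing_variance(200.0, 14.0, 1.41, 0.0, 0.0064, 4.5e-5, 1.0)
        assert got == pytest.approx((1.41 * n_active(214.0, 0.0064, 4.5e-5)) ** 2, rel=1e-12)


class TestShares:
    def test_shares_sum_to_one(self, nominal_schedule, ref_params, ref_var_params):
        mom = propagate_session_moments(nominal_schedule, ref_params, ref_var_params)
        per, overall = variance_shares(mom)
        np.testing.assert_allclose(per.sum(axis=1), 1.0, rtol=1e-12)
        assert overall.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_component_share_is_one(self, short_schedule, simple_params, simple_var_params):
        mom = propagate_session_moments(
            short_schedule, simple_params.with_(pi=0.0), simple_var_params.with_(phi=0.0)
        )
        per, overall = variance_shares(mom)
        assert overall["v_mes"] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(per["v_mes"], 1.0, rtol=1e-12)

    def test_empty_moments_rejected(self):
        with pytest.raises(ValueError):
            variance_shares([])
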