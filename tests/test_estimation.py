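"""Likelihood, transforms, and single-lactation fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from milksession.data import LactationSeries
from milksession.estimation import (
    POSITIVE,
    UNIT,
    FitConfig,
    fit,
    log_likelihood,
    transform_to_natural,
    transform_to_working,
)
from milksession.simulate import SimConfig, simulate_lactation
from milksession.variance import propagate_moment_arrays


class TestTransforms:
    @given(st.floats(min_value=1e-8, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_positive_round_trip(self, theta):
        a = transform_to_working(theta, POSITIVE)
        assert transform_to_natural(a, POSITIVE) == pytest.approx(theta, rel=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_unit_interval_round_trip(self, theta):
        a = transform_to_working(theta, UNIT)
        assert transform_to_natural(a, UNIT) == pytest.approx(theta, rel=1e-9)

    def test_unit_codomain(self):
        for a in (-20.0, -1.0, 0.0, 1.0, 5.0):
            assert 0.0 < transform_to_natural(a, UNIT) < 1.0

    def test_rejects_out_of_domain(self):
        with pytest.raises(ValueError):
            transform_to_working(-1.0, POSITIVE)
        with pytest.raises(ValueError):
            transform_to_working(1.5, UNIT)


@pytest.fixture(scope="module")
def sim_series(ref_params_mod, ref_var_params_mod):
    cfg = SimConfig(mean_params=ref_params_mod, var_params=ref_var_params_mod)
    cfg = cfg.with_(interval_jitter_sd=0.5)
    return simulate_lactation(cfg, seed=7)


@pytest.fixture(scope="module")
def ref_params_mod():
    from milksession.params import reference_params

    return reference_params()


@pytest.fixture(scope="module")
def ref_var_params_mod():
    from milksession.params import reference_var_params

    return reference_var_params()


class TestLogLikelihood:
    def test_matches_per_session_normal_densities(self, sim_series, ref_params_mod, ref_var_params_mod):
        """Brute-force summation oracle: sum of scalar normal log-pdfs."""
        a = propagate_moment_arrays(
            sim_series.schedule(ref_params_mod.delta), ref_params_mod, ref_var_params_mod
        )
        oracle = sum(
            stats.norm.logpdf(y, mu, np.sqrt(v))
            for y, mu, v in zip(sim_series.yields_kg, a["mean_measured"], a["var_total"])
        )
        got = log_likelihood(sim_series, ref_params_mod, ref_var_params_mod)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_perfect_fit_reduces_to_entropy_term(self, ref_params_mod, ref_var_params_mod):
        a_sched = LactationSeries(
            hours=np.arange(0.0, 30 * 12, 12.0),
            yields_kg=np.ones(30),
            labels=np.array(["M", "E"] * 15),
        )
        a = propagate_moment_arrays(
            a_sched.schedule(ref_params_mod.delta), ref_params_mod, ref_var_params_mod
        )
        perfect = LactationSeries(
            hours=a_sched.hours, yields_kg=a["mean_measured"], labels=a_sched.labels
        )
        got = log_likelihood(perfect, ref_params_mod, ref_var_params_mod)
        assert got == pytest.approx(-0.5 * np.sum(np.log(2 * np.pi * a["var_total"])), abs=1e-10)

    def test_single_session_matches_scalar_density(self, ref_params_mod, ref_var_params_mod):
        s = LactationSeries(hours=np.array([0.0]), yields_kg=np.array([15.0]),
                            labels=np.array(["M"]))
        a = propagate_moment_arrays(
            s.schedule(ref_params_mod.delta), ref_params_mod, ref_var_params_mod
        )
        got = log_likelihood(s, ref_params_mod, ref_var_params_mod)
        assert got == pytest.approx(
            float(stats.norm.logpdf(15.0, a["mean_measured"][0], np.sqrt(a["var_total"][0]))),
            abs=1e-12,
        )


class TestFit:
    def test_requires_enough_sessions(self):
        s = LactationSeries(hours=np.arange(0.0, 60, 12.0), yields_kg=np.full(5, 10.0),
                            labels=np.array(["M", "E", "M", "E", "M"]))
        with pytest.raises(ValueError):
            fit(s)

    def test_known_structure_fit_recovers_truth(self, sim_series, ref_params_mod, ref_var_params_mod):
        """With the true segmentation and extreme sessions supplied, the
        ML estimates land near the generating values and the CIs bracket
        the estimates."""
        cfg = FitConfig(
            segment_starts=ref_params_mod.segment_starts,
            extreme_sessions=tuple(sorted(ref_params_mod.pi_overrides)),
        )
        r = fit(sim_series, cfg)
        assert r.converged
        assert r.estimates["delta"] == pytest.approx(ref_params_mod.delta, rel=0.15)
        assert r.estimates["lambda_a"] == pytest.approx(ref_params_mod.lambda_a, rel=0.25)
        assert r.estimates["lambda_r"] == pytest.approx(ref_params_mod.lambda_r, rel=0.5)
        assert r.pl_max == pytest.approx(ref_params_mod.pl_max, rel=0.05)
        # identifiability guard: activation faster than inactivation
        assert r.estimates["lambda_a"] > r.estimates["lambda_r"]
        for name, (lo, hi) in ((k, v) for k, v in r.ci.items() if v is not None):
            assert lo <= r.estimates[name] <= hi
        # standardized residuals behave like unit-variance noise
        assert np.std(r.std_residuals) == pytest.approx(1.0, abs=0.15)
        assert r.variance_explained_ratio == pytest.approx(1.0, abs=0.2)

    def test_optimum_is_local_maximum(self, sim_series, ref_params_mod, ref_var_params_mod):
        cfg = FitConfig(segment_starts=ref_params_mod.segment_starts,
                        extreme_sessions=tuple(sorted(ref_params_mod.pi_overrides)))
        r = fit(sim_series, cfg)
        base = log_likelihood(sim_series, r.mean_params, r.var_params)
        for factor in (0.97, 1.03):
            mp = r.mean_params.with_(lambda_a=r.mean_params.lambda_a * factor)
            assert log_likelihood(sim_series, mp, r.var_params) < base
            mp = r.mean_params.with_(delta=r.mean_params.delta * factor)
            assert log_likelihood(sim_series, mp, r.var_params) < base
            vp = r.var_params.with_(phi=min(r.var_params.phi * factor, 1.0))
            assert log_likelihood(sim_series, r.mean_params, vp) < base
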