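"""Generative synthetic-lactation engine.

The model specifies first and second moments, not full distributions, so
the simulator uses positivity-respecting families matched to those
moments:

* milk produced per interval Y_P(k): Gamma with the model's mean (mean
  model) and variance V_PL + V_PA (secretion-proportion + activated-
  alveoli terms, the latter scaled by the underdispersion factor phi);
* retention split: the retained fraction F(k) is Beta with mean pi(k) and
  a variance chosen so that Y_R(k) = F(k) * (Y_P(k) + Y_R(k-1)) and
  Y_E(k) = (1 - F(k)) * (...) reproduce the propagated retention
  recursions exactly (the binomial-type S pi(1-pi) term plus pi^2 /
  (1-pi)^2 times the available-milk variance);
* measurement: Y_M(k) = Y_E(k) * exp(eps), eps ~ Normal(0, CV_M).

With every noise source zeroed the draw degenerates to the deterministic
mean model.  Sample moments across replicates converge to the variance
model's propagated moments (tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import MilkingSchedule, expected_yields
from .data import LactationSeries
from .params import MeanParams, VarParams, reference_params, reference_var_params
from .variance import propagate_moment_arrays

__all__ = ["SimConfig", "simulate_schedule", "simulate_lactation", "simulate_replicates", "recovery_harness", "reference_config"]

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Ground truth and schedule settings for synthetic lactations.

    Defaults emulate a conventional ~305-day, twice-daily lactation with
    mean intervals of 14 h (evening -> morning) and 10 h (morning ->
    evening) and interval-length variance ``var_t`` (h^2).
    """

    mean_params: MeanParams = field(default_factory=lambda: reference_params())
    var_params: VarParams = field(default_factory=reference_var_params)
    n_days: int = 305
    interval_means: tuple = (14.0, 10.0)
    interval_jitter_sd: float = 0.5
    first_label: str = "M"
    # set False to make the retained fraction exactly pi(k) (no
    # binomial-type retention noise); with all noise sources off the
    # draw degenerates to the deterministic mean model
    retention_noise: bool = True

    @property
    def n_sessions(self) -> int:
        return 2 * self.n_days

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def reference_config(n_days: int = 305) -> SimConfig:
    """Simulation preset at the reference-lactation estimates."""
    cfg = SimConfig(n_days=n_days, mean_params=reference_params(2 * n_days))
    cfg = cfg.with_(interval_jitter_sd=float(np.sqrt(cfg.var_params.var_t)))
    return cfg


def simulate_schedule(config: SimConfig, rng: np.random.Generator) -> MilkingSchedule:
    """Twice-daily schedule with jittered alternating intervals.

    The label of a session names the interval that precedes it: a morning
    session follows the long (14 h) overnight interval.  The first session
    occurs at t = delta.
    """
    if config.n_days < 1:
        raise ValueError("n_days must be >= 1")
    n = config.n_sessions
    to_morning, to_evening = config.interval_means
    labels = np.empty(n, dtype="U1")
    labels[0] = config.first_label
    for k in range(1, n):
        labels[k] = "E" if labels[k - 1] == "M" else "M"
    means = np.where(labels[1:] == "M", to_morning, to_evening)
    intervals = means + config.interval_jitter_sd * rng.standard_normal(n - 1)
    intervals = np.clip(intervals, 0.5, None)
    times = config.mean_params.delta + np.concatenate([[0.0], np.cumsum(intervals)])
    return MilkingSchedule(times, labels, config.mean_params.delta)


def _draw_chain(config, schedule, rng, size):
    """Vectorized draw of ``size`` replicate session chains.

    Returns (y_measured, y_extracted, y_residual, y_produced) arrays of
    shape (size, K).
    """
    mp, vp = config.mean_params, config.var_params
    a = propagate_moment_arrays(schedule, mp, vp)
    n = len(schedule)
    pi = mp.pi_for_sessions(n)
    mu_p, v_p = a["mean_produced"], a["var_produced"]
    # propagated available-milk moments, for the Beta fraction variance
    s_mean = a["mean_produced"] + np.concatenate([[0.0], a["mean_residual"][:-1]])
    s_var = a["var_produced"] + np.concatenate([[0.0], a["var_residual"][:-1]])
    cv = vp.cv_measurement

    y_p = np.empty((size, n))
    y_e = np.empty((size, n))
    y_r = np.empty((size, n))
    y_m = np.empty((size, n))
    resid = np.zeros(size)
    n_truncated = 0
    for k in range(n):
        if v_p[k] > 0:
            shape = mu_p[k] ** 2 / v_p[k]
            scale = v_p[k] / mu_p[k]
            yp = rng.gamma(shape, scale, size=size)
        else:
            yp = np.full(size, mu_p[k])
        avail = yp + resid
        p = pi[k]
        if p > 0 and not config.retention_noise:
            f = np.full(size, p)
        elif p > 0:
            var_f = p * (1.0 - p) * s_mean[k] / (s_var[k] + s_mean[k] ** 2)
            var_f = min(var_f, 0.999 * p * (1.0 - p))
            conc = p * (1.0 - p) / var_f - 1.0
            f = rng.beta(p * conc, (1.0 - p) * conc, size=size)
        else:
            f = np.zeros(size)
        rk = f * avail
        ek = avail - rk
        if cv > 0:
            mk = ek * np.exp(cv * rng.standard_normal(size))
        else:
            mk = ek
        neg = mk < 0
        if np.any(neg):
            n_truncated += int(neg.sum())
            mk = np.where(neg, 0.0, mk)
        y_p[:, k], y_r[:, k], y_e[:, k], y_m[:, k] = yp, rk, ek, mk
        resid = rk
    if n_truncated:
        log.info("truncated %d negative measured yields to zero", n_truncated)
    return y_m, y_e, y_r, y_p


def simulate_replicates(config: SimConfig, schedule: MilkingSchedule, n_replicates: int, rng):
    """Measured-yield matrix (n_replicates, K) on a fixed schedule."""
    y_m, _, _, _ = _draw_chain(config, schedule, rng, n_replicates)
    return y_m


def simulate_lactation(config: SimConfig, seed=None, rng: Optional[np.random.Generator] = None) -> LactationSeries:
    """One synthetic lactation with ground truth in ``series.truth``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    schedule = simulate_schedule(config, rng)
    y_m, y_e, y_r, y_p = _draw_chain(config, schedule, rng, 1)
    mp = config.mean_params
    truth = {
        "delta": mp.delta,
        "lambda_a": mp.lambda_a,
        "lambda_r": mp.lambda_r,
        "pi": mp.pi,
        "pi_overrides": dict(mp.pi_overrides),
        "pl_segments": list(mp.pl_segments),
        "segment_starts": list(mp.segment_starts),
        "pl_max": mp.pl_max,
        "phi": config.var_params.phi,
        "y_extracted": y_e[0],
        "y_residual": y_r[0],
        "y_produced": y_p[0],
        "times": schedule.times,
    }
    return LactationSeries(
        hours=schedule.times - schedule.times[0],
        yields_kg=y_m[0],
        labels=schedule.labels,
        truth=truth,
    )


def noise_free_lactation(config: SimConfig, rng=None) -> LactationSeries:
    """Deterministic mean trajectory on a nominal (jitter-free) schedule."""
    cfg = config.with_(interval_jitter_sd=0.0)
    schedule = simulate_schedule(cfg, np.random.default_rng(0))
    _, _, y_e = expected_yields(schedule, cfg.mean_params)
    return LactationSeries(
        hours=schedule.times - schedule.times[0],
        yields_kg=y_e,
        labels=schedule.labels,
    )


def recovery_harness(
    config: SimConfig,
    n_replicates: int,
    seed: int,
    two_stage: bool = True,
    fit_kwargs: Optional[dict] = None,
):
    """Simulate-and-refit study: per-parameter bias, RMSE and CI coverage.

    Each replicate draws a fresh schedule and lactation, fits it (full
    two-stage workflow by default, or a stage-1-style fit with the true
    structure when ``two_stage=False``), and records the estimates.
    Returns ``(report, estimates)``: a DataFrame indexed by parameter with
    columns truth/median/bias/rmse/coverage, and the raw per-replicate
    estimate DataFrame.
    """
    import pandas as pd

    from .estimation import FitConfig, fit as fit_one, two_stage_fit

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    mp, vp = config.mean_params, config.var_params
    truth = {
        "delta": mp.delta,
        "lambda_a": mp.lambda_a,
        "lambda_r": mp.lambda_r,
        "pi": mp.pi,
        "pl_max": mp.pl_max,
        "phi": vp.phi,
    }
    rows, covers = [], []
    for _ in range(n_replicates):
        series = simulate_lactation(config, rng=rng)
        if two_stage:
            result, _elements = two_stage_fit(series, FitConfig(**(fit_kwargs or {})))
        else:
            cfg = FitConfig(
                segment_starts=mp.segment_starts,
                extreme_sessions=tuple(sorted(mp.pi_overrides)),
                **(fit_kwargs or {}),
            )
            result = fit_one(series, cfg)
        est = {
            "delta": result.estimates["delta"],
            "lambda_a": result.estimates["lambda_a"],
            "lambda_r": result.estimates["lambda_r"],
            "pi": result.estimates["pi"],
            "pl_max": result.pl_max,
            "phi": result.estimates["phi"],
        }
        rows.append(est)
        cov = {}
        for name in ("delta", "lambda_a", "lambda_r", "pi", "phi"):
            c = result.ci.get(name)
            cov[name] = (c is not None) and (c[0] <= truth[name] <= c[1])
        # PL_max coverage uses the CI of the widest-PL segment
        pl_cis = [result.ci.get(f"pl_{i+1}") for i in range(len(result.config.segment_starts))]
        pl_est = [result.estimates[f"pl_{i+1}"] for i in range(len(result.config.segment_starts))]
        i_max = int(np.argmax(pl_est))
        c = pl_cis[i_max]
        cov["pl_max"] = (c is not None) and (c[0] <= truth["pl_max"] <= c[1])
        covers.append(cov)
    estimates = pd.DataFrame(rows)
    coverage = pd.DataFrame(covers)
    report = pd.DataFrame(
        {
            "truth": pd.Series(truth),
            "median": estimates.median(),
            "bias": estimates.mean() - pd.Series(truth),
            "rmse": np.sqrt(((estimates - pd.Series(truth)) ** 2).mean()),
            "coverage": coverage.mean(),
        }
    )
    return report, estimates
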