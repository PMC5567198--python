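"""Variance model: per-session yield variance and its decomposition.

Each measured session yield Y_M(k) = Y_E(k) * exp(eps) carries log-normal
measurement error with a known coefficient of variation CV_M (small-eps
approximation: E(Y_M) = E(Y_E), Var(eps) = CV_M^2).  The variance of the
extracted yield is propagated through the retention recursion jointly with
the residual-milk moments (E(Y_R(0)) = Var(Y_R(0)) = 0):

    Var(Y_E(k)) = S(k) pi (1-pi) + (1-pi)^2 [Var(Y_P(k)) + Var(Y_R(k-1))]
    Var(Y_R(k)) = S(k) pi (1-pi) + pi^2     [Var(Y_P(k)) + Var(Y_R(k-1))]

with S(k) = E(Y_P(k)) + E(Y_R(k-1)), and the produced-milk variance split
into a secretion-proportion term and an activated-alveoli term:

    V_PL(k) = PL_max dt(k) E(MN_A) E(beta)(1 - E(beta))
    V_PA(k) = [PL_max E(beta)]^2 dt(k) phi E(MN_A)(1 - E(MN_A))

Total session variance decomposes exactly into five non-negative named
components (six with the interval-duration term V_tim when exact milking
times are unknown):

    Var(Y_M(k)) = V_mes + V_ret + V_rec + V_pro + V_alv (+ V_tim)

where V_mes = E(Y_E)^2 CV_M^2, V_ret = S pi(1-pi) (retention split),
V_rec = (1-pi)^2 Var(Y_R(k-1)) (carryover), V_pro = (1-pi)^2 V_PL and
V_alv = (1-pi)^2 V_PA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MilkingSchedule, mean_active_fraction, n_active
from .params import MeanParams, VarParams

__all__ = [
    "SessionMoments",
    "production_moments",
    "timing_variance",
    "propagate_session_moments",
    "propagate_moment_arrays",
    "variance_shares",
    "decomposition_frame",
]

COMPONENTS = ("v_mes", "v_ret", "v_rec", "v_pro", "v_alv", "v_tim")


@dataclass(frozen=True)
class SessionMoments:
    """First two moments of one session's yields plus variance components.

    All means in kg, variances in kg^2.  ``var_total`` equals the sum of
    the component fields (``v_tim`` is zero unless interval-uncertainty
    mode is on).
    """

    k: int
    t: float
    mean_measured: float
    var_total: float
    v_mes: float
    v_ret: float
    v_rec: float
    v_pro: float
    v_alv: float
    v_tim: float
    mean_produced: float
    var_produced: float
    mean_residual: float
    var_residual: float


def production_moments(
    t_prev: float,
    t_now: float,
    pl_max: float,
    beta: float,
    phi: float,
    lambda_a: float,
    lambda_r: float,
):
    """Moments of milk produced on one interval: (mean, V_PL, V_PA)."""
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    dt = t_now - t_prev
    m = float(mean_active_fraction(t_prev, t_now, lambda_a, lambda_r))
    mean = pl_max * beta * dt * m
    v_pl = pl_max * dt * m * beta * (1.0 - beta)
    v_pa = (pl_max * beta) ** 2 * dt * phi * m * (1.0 - m)
    return mean, v_pl, v_pa


def timing_variance(
    t_prev: float,
    nominal_dt: float,
    pl_k: float,
    pi_k: float,
    lambda_a: float,
    lambda_r: float,
    var_t: float,
) -> float:
    """Variance contributed by uncertain interval duration, V_tim(k).

    First-order propagation of the interval length through the secretion
    integral: dY_P/d(dt) = PL(k) * N_A(t_prev + dt), evaluated at the
    nominal interval length for the session's label, times Var_T.
    """
    sens = pl_k * n_active(t_prev + nominal_dt, lambda_a, lambda_r)
    return (1.0 - pi_k) ** 2 * sens**2 * var_t


def propagate_moment_arrays(
    schedule: MilkingSchedule,
    params: MeanParams,
    var_params: VarParams,
    interval_uncertainty: bool = False,
):
    """Vectorized propagation of all session moments.

    Returns a dict of equal-length arrays: means/variances of Y_P, Y_R,
    Y_E = Y_M, the six variance components and ``var_total``.  This is the
    computational core shared by the likelihood, the simulator and the
    reporting layer.
    """
    n = len(schedule)
    t0, t1 = schedule.prev_times, schedule.times
    dt = t1 - t0
    la, lr = params.lambda_a, params.lambda_r
    pl = params.pl_for_sessions(n)
    beta = pl / params.pl_max
    pi = params.pi_for_sessions(n)
    m = np.asarray(mean_active_fraction(t0, t1, la, lr))
    mu_p = params.pl_max * beta * dt * m
    v_pl = params.pl_max * dt * m * beta * (1.0 - beta)
    v_pa = (params.pl_max * beta) ** 2 * dt * var_params.phi * m * (1.0 - m)
    v_p = v_pl + v_pa

    if interval_uncertainty:
        nominal = np.where(
            schedule.labels == "M",
            var_params.nominal_deltas[0],
            var_params.nominal_deltas[1],
        )
        sens = pl * np.asarray(n_active(t0 + nominal, la, lr))
        v_tim = (1.0 - pi) ** 2 * sens**2 * var_params.var_t
    else:
        v_tim = np.zeros(n)

    cv2 = var_params.cv_measurement**2
    e_e = np.empty(n)
    e_r = np.empty(n)
    v_e = np.empty(n)
    v_r = np.empty(n)
    v_mes = np.empty(n)
    v_ret = np.empty(n)
    v_rec = np.empty(n)
    er_prev = 0.0
    vr_prev = 0.0
    mu_l, vp_l, pi_l, vt_l = mu_p.tolist(), v_p.tolist(), pi.tolist(), v_tim.tolist()
    for k in range(n):
        p = pi_l[k]
        s = mu_l[k] + er_prev
        va = vp_l[k] + vr_prev
        one_m = 1.0 - p
        binom = s * p * one_m
        ee = one_m * s
        e_e[k] = ee
        v_ret[k] = binom
        v_rec[k] = one_m * one_m * vr_prev
        v_e[k] = binom + one_m * one_m * va
        v_mes[k] = ee * ee * cv2
        e_r[k] = p * s
        vr_prev = binom + p * p * va
        v_r[k] = vr_prev
        er_prev = e_r[k]

    v_pro = (1.0 - pi) ** 2 * v_pl
    v_alv = (1.0 - pi) ** 2 * v_pa
    var_total = v_mes + v_ret + v_rec + v_pro + v_alv + v_tim
    return {
        "t": t1,
        "dt": dt,
        "mean_produced": mu_p,
        "var_produced": v_p,
        "mean_residual": e_r,
        "var_residual": v_r,
        "mean_extracted": e_e,
        "var_extracted": v_e + v_tim,
        "mean_measured": e_e,
        "var_total": var_total,
        "v_mes": v_mes,
        "v_ret": v_ret,
        "v_rec": v_rec,
        "v_pro": v_pro,
        "v_alv": v_alv,
        "v_tim": v_tim,
    }


def propagate_session_moments(
    schedule: MilkingSchedule,
    params: MeanParams,
    var_params: VarParams,
    interval_uncertainty: bool = False,
):
    """Per-session moments as a list of :class:`SessionMoments`."""
    a = propagate_moment_arrays(schedule, params, var_params, interval_uncertainty)
    return [
        SessionMoments(
            k=k + 1,
            t=float(a["t"][k]),
            mean_measured=float(a["mean_measured"][k]),
            var_total=float(a["var_total"][k]),
            v_mes=float(a["v_mes"][k]),
            v_ret=float(a["v_ret"][k]),
            v_rec=float(a["v_rec"][k]),
            v_pro=float(a["v_pro"][k]),
            v_alv=float(a["v_alv"][k]),
            v_tim=float(a["v_tim"][k]),
            mean_produced=float(a["mean_produced"][k]),
            var_produced=float(a["var_produced"][k]),
            mean_residual=float(a["mean_residual"][k]),
            var_residual=float(a["var_residual"][k]),
        )
        for k in range(len(schedule))
    ]


def variance_shares(moments):
    """Relative contribution of each variance component.

    Returns ``(per_session, overall)``: a DataFrame of per-session shares
    (rows sum to 1) and a Series of whole-lactation shares, each component
    summed across sessions and divided by the summed total variance.
    """
    if len(moments) == 0:
        raise ValueError("moments must be non-empty")
    comp = {c: np.array([getattr(mo, c) for mo in moments]) for c in COMPONENTS}
    total = np.array([mo.var_total for mo in moments])
    if np.any(total <= 0):
        raise ValueError("variance shares undefined where total variance is zero")
    per = pd.DataFrame({c: comp[c] / total for c in COMPONENTS})
    per.index = [mo.k for mo in moments]
    overall = pd.Series({c: comp[c].sum() / total.sum() for c in COMPONENTS})
    return per, overall


def decomposition_frame(moments) -> pd.DataFrame:
    """Export-ready table: k, t, mean, total variance, components, shares."""
    per, _ = variance_shares(moments)
    df = pd.DataFrame(
        {
            "k": [mo.k for mo in moments],
            "t_hours": [mo.t for mo in moments],
            "mean_kg": [mo.mean_measured for mo in moments],
            "var_total": [mo.var_total for mo in moments],
        }
    )
    for c in COMPONENTS:
        df[c] = [getattr(mo, c) for mo in moments]
    for c in COMPONENTS:
        df[f"share_{c}"] = per[c].to_numpy()
    return df
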