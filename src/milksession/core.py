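"""Deterministic mean model of per-session milk yield.

Three alveolar classes — non-activated N_I, activated N_A, inactivated
N_R — evolve by first-order kinetics from N_I(0) = 1:

    dN_I/dt = -lambda_A * N_I
    dN_A/dt = +lambda_A * N_I - lambda_R * N_A
    dN_R/dt = +lambda_R * N_A

with the closed-form solution N_I(t) = exp(-lambda_A t) and
N_A(t) = lambda_A/(lambda_A - lambda_R) * [exp(-lambda_R t) - exp(-lambda_A t)].

Milk secreted between sessions k-1 and k is linear in the activated
proportion, Y_P(k) = PL(k) * integral of N_A over the interval, and each
milking extracts all available milk except a retained fraction pi(k):

    Y_R(k) = pi(k) * (Y_P(k) + Y_R(k-1))
    Y_E(k) = (1 - pi(k)) * (Y_P(k) + Y_R(k-1))

Time is in hours since lactation start; the first session occurs at
t(1) = delta with an empty compartment at t = 0 (Y_R(0) = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MeanParams

__all__ = [
    "AlveolarState",
    "MilkingSchedule",
    "SessionYields",
    "alveolar_state",
    "active_fraction_integral",
    "mean_active_fraction",
    "secreted_between_sessions",
    "extraction_series",
    "expected_yields",
]

# relative |lambda_a - lambda_r| below which the analytic confluent limit
# N_A = lambda_a * t * exp(-lambda_a * t) is used
_DEGENERACY_RTOL = 1e-10


@dataclass(frozen=True)
class AlveolarState:
    """Proportions of the three alveolar classes at time ``t`` (hours)."""

    t: float
    n_inactive: float
    n_active: float
    n_retired: float


@dataclass(frozen=True)
class SessionYields:
    """Milk bookkeeping for one session: produced, retained, extracted (kg)."""

    y_produced: float
    y_residual: float
    y_extracted: float


class MilkingSchedule:
    """Ordered milking times in hours since lactation start.

    Parameters
    ----------
    times : array-like
        Strictly increasing session times t(k), hours since lactation
        start; ``times[0] = delta``.
    labels : array-like of str
        'M' (morning) or 'E' (evening) per session.
    delta : float
        Hours between lactation start and the first session.
    """

    def __init__(self, times, labels, delta: float):
        self.times = np.asarray(times, dtype=float)
        self.labels = np.asarray(labels, dtype="U1")
        self.delta = float(delta)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValueError("times must be a non-empty 1-d sequence")
        if len(self.labels) != len(self.times):
            raise ValueError("labels and times length mismatch")
        if self.times[0] <= 0:
            raise ValueError("first session time must be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("session times must be strictly increasing")
        if not np.isclose(self.times[0], self.delta):
            raise ValueError("times[0] must equal delta")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def prev_times(self) -> np.ndarray:
        """t(k-1) per session, with t(0) = 0 (lactation start)."""
        return np.concatenate([[0.0], self.times[:-1]])

    @property
    def intervals(self) -> np.ndarray:
        """Interval lengths t(k) - t(k-1), hours; first is delta."""
        return self.times - self.prev_times

    @classmethod
    def from_hours_since_first(cls, hours, labels, delta: float) -> "MilkingSchedule":
        """Build from observed times expressed as hours since the first
        session (hours[0] = 0), shifted by the latency ``delta``."""
        hours = np.asarray(hours, dtype=float)
        if hours[0] != 0:
            raise ValueError("hours since first session must start at 0")
        if delta <= 0:
            raise ValueError("delta must be > 0")
        return cls(hours + delta, labels, delta)


def _is_degenerate(lambda_a: float, lambda_r: float) -> bool:
    return abs(lambda_a - lambda_r) < _DEGENERACY_RTOL * lambda_a


def n_active(t, lambda_a: float, lambda_r: float):
    """Proportion of activated alveoli N_A(t); works on scalars or arrays.

    Evaluated as lambda_a * exp(-lambda_r t) * (-expm1(-(lambda_a -
    lambda_r) t)) / (lambda_a - lambda_r), which is free of catastrophic
    cancellation for any rate separation; the confluent limit
    lambda_a * t * exp(-lambda_a t) covers the exactly-equal case.
    """
    t = np.asarray(t, dtype=float)
    d = lambda_a - lambda_r
    if _is_degenerate(lambda_a, lambda_r):
        out = lambda_a * t * np.exp(-lambda_a * t)
    else:
        out = (lambda_a / d) * np.exp(-lambda_r * t) * (-np.expm1(-d * t))
    return out if out.ndim else float(out)


def alveolar_state(t: float, lambda_a: float, lambda_r: float) -> AlveolarState:
    """Closed-form alveolar class proportions at time ``t`` hours.

    Near the confluent case lambda_a == lambda_r the analytic limit
    N_A = lambda_a * t * exp(-lambda_a * t) is used.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if lambda_a <= 0 or lambda_r < 0:
        raise ValueError("lambda_a must be > 0 and lambda_r >= 0")
    ni = float(np.exp(-lambda_a * t))
    na = float(n_active(t, lambda_a, lambda_r))
    return AlveolarState(t=t, n_inactive=ni, n_active=na, n_retired=1.0 - ni - na)


def _exp_diff(lmbda: float, t0, t1):
    """(1/l) * [exp(-l*t0) - exp(-l*t1)], with the l -> 0 limit t1 - t0."""
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if lmbda == 0.0:
        return t1 - t0
    # exp(-l t0) * (1 - exp(-l (t1-t0))) / l, stable for small l*(t1-t0)
    return np.exp(-lmbda * t0) * (-np.expm1(-lmbda * (t1 - t0))) / lmbda


def active_fraction_integral(t_prev, t_now, lambda_a: float, lambda_r: float):
    """Integral of N_A(x) dx over [t_prev, t_now] (hours); array-friendly."""
    t_prev = np.asarray(t_prev, dtype=float)
    t_now = np.asarray(t_now, dtype=float)
    if np.any(t_prev < 0) or np.any(t_now <= t_prev):
        raise ValueError("require 0 <= t_prev < t_now")
    if lambda_a <= 0 or lambda_r < 0:
        raise ValueError("lambda_a must be > 0 and lambda_r >= 0")
    # near-confluent rates: the w_R - w_A bracket cancels catastrophically
    # once |d| * t is tiny, while the confluent-limit error is O(d * t);
    # crossing over at |d| * t ~ 1e-8 keeps both below ~1e-8 relative
    d_scale = abs(lambda_a - lambda_r) * float(np.max(t_now))
    if _is_degenerate(lambda_a, lambda_r) or d_scale < 1e-8:
        a = lambda_a
        # integral of a*x*exp(-a*x) = [-(x + 1/a) exp(-a x)]
        g0 = (t_prev + 1.0 / a) * np.exp(-a * t_prev)
        g1 = (t_now + 1.0 / a) * np.exp(-a * t_now)
        out = a * (g0 - g1)
    else:
        w_r = _exp_diff(lambda_r, t_prev, t_now)
        w_a = _exp_diff(lambda_a, t_prev, t_now)
        out = (lambda_a / (lambda_a - lambda_r)) * (w_r - w_a)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def mean_active_fraction(t_prev, t_now, lambda_a: float, lambda_r: float):
    """Time-averaged activated proportion E(MN_A) over [t_prev, t_now]."""
    return active_fraction_integral(t_prev, t_now, lambda_a, lambda_r) / (
        np.asarray(t_now, dtype=float) - np.asarray(t_prev, dtype=float)
    )


def secreted_between_sessions(
    t_prev: float, t_now: float, params: MeanParams, segment_pl: float
) -> float:
    """Expected milk secreted (kg) on [t_prev, t_now] at secretion rate
    ``segment_pl`` (kg/h): PL * integral of N_A."""
    if segment_pl < 0:
        raise ValueError("segment_pl must be >= 0")
    return segment_pl * float(
        active_fraction_integral(t_prev, t_now, params.lambda_a, params.lambda_r)
    )


def expected_yields(schedule: MilkingSchedule, params: MeanParams):
    """Vectorized mean trajectory: arrays (y_produced, y_residual, y_extracted).

    Iterates the retention recursion with Y_R(0) = 0; milk is conserved at
    every session: Y_E(k) + Y_R(k) = Y_P(k) + Y_R(k-1).
    """
    n = len(schedule)
    pl = params.pl_for_sessions(n)
    pi = params.pi_for_sessions(n)
    integ = active_fraction_integral(
        schedule.prev_times, schedule.times, params.lambda_a, params.lambda_r
    )
    y_p = pl * np.asarray(integ)
    y_r = np.empty(n)
    y_e = np.empty(n)
    resid = 0.0
    yp_l, pi_l = y_p.tolist(), pi.tolist()
    for k in range(n):
        avail = yp_l[k] + resid
        resid = pi_l[k] * avail
        y_r[k] = resid
        y_e[k] = avail - resid
    return y_p, y_r, y_e


def extraction_series(schedule: MilkingSchedule, params: MeanParams):
    """Per-session milk bookkeeping as a list of :class:`SessionYields`."""
    pi = params.pi_for_sessions(len(schedule))
    if np.any(pi < 0) or np.any(pi >= 1):
        raise ValueError("pi(k) must lie in [0, 1)")
    y_p, y_r, y_e = expected_yields(schedule, params)
    return [
        SessionYields(y_produced=float(p), y_residual=float(r), y_extracted=float(e))
        for p, r, e in zip(y_p, y_r, y_e)
    ]
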