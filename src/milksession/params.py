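"""Parameter containers for the milking-session yield model.

The mean model is governed by five kinds of quantities:

* ``delta`` — hours between the (unobserved) start of lactation and the
  first milking session,
* ``lambda_a`` / ``lambda_r`` — alveolar activation / inactivation rates
  (per hour), constant over the lactation,
* ``pi`` — milk retention proportion per session, a baseline value plus
  optional per-session overrides for sessions with extreme retention,
* ``pl_segments`` — the secretion-rate parameter PL(k) (kg/h), piecewise
  constant over interval segments; ``beta(k) = PL(k)/PL_max`` is the
  derived secretion proportion.

The variance model adds a fixed measurement coefficient of variation, an
underdispersion factor ``phi`` scaling the activated-alveoli variance term,
and (optionally) the variance of interval duration when exact milking
times are unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MeanParams", "VarParams", "reference_params", "reference_var_params"]


@dataclass
class MeanParams:
    """Estimable parameters of the deterministic mean model.

    Parameters
    ----------
    delta : float
        Hours between lactation start and the first milking session (>= 0).
    lambda_a : float
        Alveolar activation rate, per hour (> 0).
    lambda_r : float
        Alveolar inactivation rate, per hour (>= 0).
    pi : float
        Baseline milk retention proportion in [0, 1).
    pl_segments : sequence of float
        Secretion-rate parameter PL for each segment, kg/h (> 0).
    segment_starts : sequence of int
        1-based session index opening each segment; must start with 1 and
        be strictly increasing.  Length matches ``pl_segments``.
    pi_overrides : dict[int, float]
        Session-specific retention proportions keyed by 1-based session
        number (extreme-retention sessions).
    """

    delta: float
    lambda_a: float
    lambda_r: float
    pi: float
    pl_segments: tuple = (1.0,)
    segment_starts: tuple = (1,)
    pi_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pl_segments = tuple(float(p) for p in self.pl_segments)
        self.segment_starts = tuple(int(s) for s in self.segment_starts)
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.lambda_a <= 0 or self.lambda_r < 0:
            raise ValueError("lambda_a must be > 0 and lambda_r >= 0")
        if not 0.0 <= self.pi < 1.0:
            raise ValueError("pi must lie in [0, 1)")
        if len(self.pl_segments) != len(self.segment_starts):
            raise ValueError("pl_segments and segment_starts length mismatch")
        if self.segment_starts[0] != 1 or any(
            b >= a for a, b in zip(self.segment_starts[1:], self.segment_starts)
        ):
            raise ValueError("segment_starts must begin at 1 and increase strictly")
        if any(p <= 0 for p in self.pl_segments):
            raise ValueError("PL values must be > 0")
        for k, v in self.pi_overrides.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"pi override for session {k} outside [0, 1)")

    @property
    def pl_max(self) -> float:
        """Maximum secretion-rate parameter over segments, kg/h."""
        return max(self.pl_segments)

    @property
    def beta_segments(self) -> np.ndarray:
        """Secretion proportions beta = PL / PL_max per segment, in (0, 1]."""
        return np.asarray(self.pl_segments) / self.pl_max

    def pl_for_sessions(self, n_sessions: int) -> np.ndarray:
        """PL(k) for k = 1..n_sessions as an array."""
        starts = np.asarray(self.segment_starts)
        seg_idx = np.searchsorted(starts, np.arange(1, n_sessions + 1), side="right") - 1
        return np.asarray(self.pl_segments)[seg_idx]

    def pi_for_sessions(self, n_sessions: int) -> np.ndarray:
        """pi(k) for k = 1..n_sessions (baseline plus overrides)."""
        out = np.full(n_sessions, self.pi)
        for k, v in self.pi_overrides.items():
            if 1 <= k <= n_sessions:
                out[k - 1] = v
        return out

    def with_(self, **kwargs) -> "MeanParams":
        return replace(self, **kwargs)


@dataclass
class VarParams:
    """Parameters of the variance model.

    ``cv_measurement`` is the a-priori coefficient of variation of the
    yield-recording device (default 0.025, i.e. 2.5 %).  ``phi`` in (0, 1]
    scales the activated-alveoli variance term and captures the
    underdispersion caused by interdependence among alveoli.  ``var_t``
    (h^2) and ``nominal_deltas`` (evening->morning, morning->evening hours)
    only matter in interval-uncertainty mode, where exact milking times are
    unknown and only the nominal schedule is available.
    """

    phi: float = 0.5
    cv_measurement: float = 0.025
    var_t: float = 0.25
    nominal_deltas: tuple = (14.0, 10.0)

    def __post_init__(self):
        if self.cv_measurement < 0:
            raise ValueError("cv_measurement must be >= 0")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.var_t < 0:
            raise ValueError("var_t must be >= 0")

    def with_(self, **kwargs) -> "VarParams":
        return replace(self, **kwargs)


def reference_params(n_sessions: int = 610) -> MeanParams:
    """Reference parameter set: the second lactation of a healthy
    Montbéliarde cow milked twice daily for ~305 days.

    delta = 70.98 h, lambda_a = 64e-4 /h, lambda_r = 45e-6 /h, baseline
    retention 0.04 with extreme retention 0.28 at sessions 33 and 36, and
    five secretion-rate segments PL = (1.41, 1.32, 1.16, 1.02, 0.90) kg/h
    (beta = 1.00, 0.94, 0.82, 0.72, 0.64).  The segment boundaries are not
    part of the published estimates.  Because beta captures event-driven
    secretion regimes (diet changes, grazing, udder state) — departures
    from the smooth alveolar decline that lambda_A/lambda_R already model —
    the preset uses an event-like placement: a long plateau over peak and
    mid lactation, then progressively shorter late-lactation regimes
    (segment starts at fractions 0, 0.30, 0.65, 0.80, 0.90 of the session
    count).
    """
    fracs = (0.0, 0.30, 0.65, 0.80, 0.90)
    bounds = np.array([1 + round(f * n_sessions) for f in fracs], dtype=int)
    return MeanParams(
        delta=70.98,
        lambda_a=64e-4,
        lambda_r=45e-6,
        pi=0.04,
        pl_segments=(1.41, 1.32, 1.16, 1.02, 0.90),
        segment_starts=tuple(bounds),
        pi_overrides={33: 0.28, 36: 0.28},
    )


def reference_var_params() -> VarParams:
    """Variance parameters of the reference lactation (phi = 0.54)."""
    return VarParams(phi=0.54, cv_measurement=0.025, var_t=0.25)
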