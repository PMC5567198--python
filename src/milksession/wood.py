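"""Wood's gamma lactation curve — the historical daily-yield comparator.

Daily yield on day x is a * x**b * exp(-c * x); the curve peaks at day
b/c with height a * (b/c)**b * exp(-b).  Parameters are fitted by
nonlinear least squares (the model carries i.i.d. additive error by
assumption — an assumption that per-session carryover violates, which is
why Wood residuals on session-model data are autocorrelated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .diagnostics import default_bp_lag, validate_residuals

__all__ = ["WoodParams", "wood_curve", "fit_wood", "wood_summaries"]


@dataclass(frozen=True)
class WoodParams:
    """Wood curve parameters: scale a (kg/day), shape b, decay c (1/day)."""

    a: float
    b: float
    c: float

    @property
    def peak_day(self) -> float:
        if self.b <= 0 or self.c <= 0:
            raise ValueError("peak defined only for b > 0 and c > 0")
        return self.b / self.c

    @property
    def peak_yield(self) -> float:
        x = self.peak_day
        return self.a * x**self.b * np.exp(-self.b)


def wood_curve(day, params: WoodParams):
    """Wood daily yield a * x^b * exp(-c x); ``day`` scalar or array > 0."""
    x = np.asarray(day, dtype=float)
    if np.any(x <= 0):
        raise ValueError("day must be > 0")
    out = params.a * x**params.b * np.exp(-params.c * x)
    return out if out.ndim else float(out)


@dataclass
class WoodFit:
    params: WoodParams
    se: tuple
    residuals: np.ndarray
    rss: float
    bp_pvalue: Optional[float]
    converged: bool

    def ci95(self):
        z = 1.959963984540054
        p = (self.params.a, self.params.b, self.params.c)
        return {
            name: (v - z * s, v + z * s) for name, v, s in zip("abc", p, self.se)
        }


def fit_wood(days, daily_yields) -> WoodFit:
    """Least-squares Wood fit to daily yields.

    Starting values come from the log-linearized regression
    log y = log a + b log x - c x on the positive yields.  The returned
    fit includes a Box-Pierce test of the residuals, since serial
    correlation is the Wood model's characteristic defect on session-level
    physiology.
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(daily_yields, dtype=float)
    if len(x) != len(y):
        raise ValueError("days and yields must align")
    if len(x) < 10:
        raise ValueError("need at least 10 daily observations")
    pos = y > 0
    X = np.column_stack([np.ones(pos.sum()), np.log(x[pos]), -x[pos]])
    coef, *_ = np.linalg.lstsq(X, np.log(y[pos]), rcond=None)
    p0 = [float(np.exp(coef[0])), float(coef[1]), float(coef[2])]

    def model(xx, a, b, c):
        return a * xx**b * np.exp(-c * xx)

    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
        converged = np.all(np.isfinite(pcov))
    except RuntimeError:
        raise RuntimeError("Wood least-squares fit did not converge")
    params = WoodParams(*[float(v) for v in popt])
    resid = y - model(x, *popt)
    se = tuple(np.sqrt(np.diag(pcov)))
    bp = None
    if len(resid) >= 30 and np.ptp(resid) > 0:
        sd = resid.std(ddof=3)
        _, bp = validate_residuals(resid / sd, lag=default_bp_lag(len(resid)))
    return WoodFit(
        params=params,
        se=se,
        residuals=resid,
        rss=float(np.sum(resid**2)),
        bp_pvalue=bp,
        converged=bool(converged),
    )


def wood_summaries(params: WoodParams, lactation_days: int) -> dict:
    """Peak day (b/c), peak yield, and total production by daily summation
    over days 1..lactation_days."""
    days = np.arange(1, lactation_days + 1, dtype=float)
    total = float(np.sum(wood_curve(days, params)))
    return {
        "peak_day": float(params.peak_day),
        "peak_yield_kg": float(params.peak_yield),
        "total_kg": total,
    }
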