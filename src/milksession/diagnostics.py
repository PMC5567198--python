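"""Residual validation, daily aggregation and goodness-of-fit summaries.

Residuals standardized by the fitted mean/variance model are standard
normal and serially uncorrelated when the model is correct; normality is
checked with a Kolmogorov-Smirnov test against N(0, 1) (the residuals are
standardized by construction, so no moments are estimated from them) and
autocorrelation with a Box-Pierce portmanteau test.  Daily means and
variances are obtained by summing a day's sessions, which is valid
exactly when the session residuals are uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox

__all__ = [
    "DiagnosticsReport",
    "default_bp_lag",
    "validate_residuals",
    "aggregate_daily",
    "fit_summaries",
]


@dataclass
class DiagnosticsReport:
    ks_pvalue: float
    box_pierce_pvalue: float
    bp_lag: int
    pearson_r: float
    variance_explained_ratio: float
    daily: pd.DataFrame


def default_bp_lag(n: int) -> int:
    """Default Box-Pierce lag: min(20, n // 4)."""
    return max(1, min(20, n // 4))


def validate_residuals(std_residuals, lag: int | None = None):
    """(KS p-value vs N(0,1), Box-Pierce p-value) of the residuals."""
    z = np.asarray(std_residuals, dtype=float)
    if len(z) < 30:
        raise ValueError("need at least 30 residuals")
    if np.ptp(z) == 0:
        raise ValueError("degenerate (constant) residuals")
    if lag is None:
        lag = default_bp_lag(len(z))
    ks = stats.kstest(z, "norm")
    bp = acorr_ljungbox(z, lags=[lag], boxpierce=True)
    return float(ks.pvalue), float(bp["bp_pvalue"].iloc[0])


def aggregate_daily(session_means, session_vars, day_index) -> pd.DataFrame:
    """Daily mean and variance by summing each calendar day's sessions.

    Valid when session residuals are uncorrelated (variances add).  Days
    with a single session pass through unchanged.
    """
    df = pd.DataFrame(
        {
            "day": np.asarray(day_index),
            "mean": np.asarray(session_means, dtype=float),
            "var": np.asarray(session_vars, dtype=float),
        }
    )
    out = df.groupby("day", as_index=False).agg(
        mean_kg=("mean", "sum"), var_kg2=("var", "sum"), n_sessions=("mean", "size")
    )
    return out


def _smoothed_peak(daily_means: np.ndarray, window: int = 7):
    """(peak_day 1-based, peak_yield) from a centered moving average."""
    n = len(daily_means)
    w = min(window, n)
    kernel = np.ones(w) / w
    sm = np.convolve(daily_means, kernel, mode="same")
    # edges of 'same' convolution average fewer real points; renormalize
    counts = np.convolve(np.ones(n), kernel, mode="same")
    sm = sm / counts
    i = int(np.argmax(sm))
    return i + 1, float(sm[i])


def fit_summaries(
    observed,
    fitted,
    model_var=None,
    day_index=None,
    smoothing_window: int = 7,
) -> dict:
    """Session-level goodness of fit and lactation-scale summaries.

    Returns Pearson r of observed vs fitted session yields, the
    variance-explained ratio (summed model variance over summed squared
    raw residuals; ~1 for a well-specified model), total yields, and —
    when ``day_index`` is given — the peak day and peak daily yield of a
    7-day centered moving average of the daily totals.
    """
    obs = np.asarray(observed, dtype=float)
    fit_ = np.asarray(fitted, dtype=float)
    if obs.shape != fit_.shape:
        raise ValueError("observed and fitted lengths differ")
    if np.ptp(fit_) == 0 or np.ptp(obs) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(obs, fit_)[0, 1])
    out = {
        "pearson_r": r,
        "total_observed_kg": float(obs.sum()),
        "total_fitted_kg": float(fit_.sum()),
    }
    if model_var is not None:
        rss = float(np.sum((obs - fit_) ** 2))
        out["variance_explained_ratio"] = float(np.sum(model_var) / rss) if rss > 0 else np.inf
    if day_index is not None:
        daily = aggregate_daily(fit_, np.zeros_like(fit_), day_index)
        peak_day, peak_yield = _smoothed_peak(
            daily["mean_kg"].to_numpy(), smoothing_window
        )
        out["peak_day"] = int(daily["day"].iloc[peak_day - 1]) + 1
        out["peak_yield_kg"] = peak_yield
    return out
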