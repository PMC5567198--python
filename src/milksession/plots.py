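"""Figure export: observed vs fitted, residual ECDF, PACF stem plot."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy import stats  # noqa: E402
from statsmodels.tsa.stattools import pacf  # noqa: E402

__all__ = ["plot_observed_vs_fitted", "plot_residual_ecdf", "plot_residual_pacf"]


def plot_observed_vs_fitted(series, result, path, wood_daily=None):
    """Observed and model-fitted session yields over the lactation, with a
    95% band; optionally overlays a Wood daily curve divided over its two
    sessions for visual comparison."""
    fig, ax = plt.subplots(figsize=(9, 4))
    t = series.hours / 24.0
    ax.plot(t, series.yields_kg, "k-", lw=0.6, alpha=0.7, label="observed")
    ax.plot(t, result.fitted_mean, "g-", lw=1.2, label="model")
    half = 1.96 * np.sqrt(result.fitted_var)
    ax.fill_between(
        t, result.fitted_mean - half, result.fitted_mean + half,
        color="g", alpha=0.15, label="95% band",
    )
    if wood_daily is not None:
        days, daily = wood_daily
        ax.plot(days, daily / 2.0, "r--", lw=1.0, label="Wood (per session)")
    ax.set_xlabel("days since first milking")
    ax.set_ylabel("session yield (kg)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_residual_ecdf(std_residuals, path):
    """Empirical CDF of standardized residuals vs the N(0,1) CDF."""
    z = np.sort(np.asarray(std_residuals))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(z, np.arange(1, len(z) + 1) / len(z), where="post", label="residual ECDF")
    grid = np.linspace(z.min() - 0.5, z.max() + 0.5, 200)
    ax.plot(grid, stats.norm.cdf(grid), "r-", lw=1, label="N(0,1)")
    ax.set_xlabel("standardized residual")
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_residual_pacf(std_residuals, path, nlags=20):
    """Partial autocorrelation of the residual sequence with 95% bounds."""
    z = np.asarray(std_residuals)
    vals = pacf(z, nlags=min(nlags, len(z) // 3), method="ywm")
    fig, ax = plt.subplots(figsize=(6, 4))
    lags = np.arange(1, len(vals))
    ax.stem(lags, vals[1:])
    bound = 1.96 / np.sqrt(len(z))
    ax.axhline(bound, color="r", ls="--", lw=0.8)
    ax.axhline(-bound, color="r", ls="--", lw=0.8)
    ax.set_xlabel("lag (sessions)")
    ax.set_ylabel("partial autocorrelation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
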