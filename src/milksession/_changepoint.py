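"""Exact mean/variance changepoint segmentation for residual sequences.

PELT-style dynamic programming under the Gaussian cost
``C(x[i:j]) = (j-i) * (log(2*pi) + log(sigma2_hat) + 1)`` (twice the
negative maximized log-likelihood with segment-specific mean and
variance).  A split is accepted when it lowers the penalized objective;
the default penalty is the asymptotic critical value of the maximal
likelihood-ratio statistic for a single mean/variance change at
significance ``alpha`` (Gumbel limit of Csorgo & Horvath with p = 2
changing parameters), so the procedure controls the family-wise
false-alarm rate at roughly ``alpha`` on white-noise input.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["meanvar_penalty", "pelt_meanvar"]

_VAR_FLOOR = 1e-12


def meanvar_penalty(n: int, alpha: float = 0.05, p: int = 2) -> float:
    """Asymptotic penalty (on the 2*log-likelihood scale) for detecting a
    single change in mean and variance at level ``alpha`` in ``n`` points.

    Derived from P(sqrt(Z_n)*a - b <= t) -> exp(-2 e^{-t}) with
    a = sqrt(2 log log n), b = 2 log log n + (p/2) log log log n
    - log Gamma(p/2); the returned value is the squared critical value of
    sqrt(Z_n).
    """
    if n < 20:
        raise ValueError("asymptotic penalty needs n >= 20")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    x = math.log(n)
    a = math.sqrt(2.0 * math.log(x))
    b = 2.0 * math.log(x) + (p / 2.0) * math.log(math.log(x)) - math.lgamma(p / 2.0)
    t = -math.log(-0.5 * math.log(1.0 - alpha))
    return ((t + b) / a) ** 2


def pelt_meanvar(x, penalty: float, min_size: int = 30):
    """Optimal penalized segmentation of ``x`` by mean and variance.

    Returns the 0-based start indices of the segments (always beginning
    with 0).  Sequences shorter than ``2 * min_size`` are returned as a
    single segment.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * min_size:
        return [0]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    log2pi = math.log(2.0 * math.pi)

    def seg_cost(starts, end):
        """Vectorized cost of segments [s, end) for an array of starts."""
        m = end - starts
        s1 = cs[end] - cs[starts]
        s2 = cs2[end] - cs2[starts]
        var = np.maximum(s2 / m - (s1 / m) ** 2, _VAR_FLOOR)
        return m * (log2pi + np.log(var) + 1.0)

    best = np.full(n + 1, np.inf)
    best[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    # candidate last-changepoint positions: 0 or >= min_size
    for end in range(min_size, n + 1):
        starts = np.arange(0, end - min_size + 1)
        starts = starts[(starts == 0) | (starts >= min_size)]
        obj = best[starts] + seg_cost(starts, end) + penalty
        j = int(np.argmin(obj))
        best[end] = obj[j]
        prev[end] = starts[j]

    # backtrack
    bounds = []
    end = n
    while end > 0:
        bounds.append(prev[end])
        end = prev[end]
    return sorted(bounds)
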