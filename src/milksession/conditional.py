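"""Residual-driven discovery of conditional elements.

Two kinds of lactation-period factors surface as structure in the
standardized residuals of an initial constant-PL, constant-pi fit:

* sessions with *extreme milk retention*, appearing as individually
  extreme residuals (two-sided standard-normal tail probability below
  ``alpha_extreme``, default 0.001), and
* *secretion-rate regimes*, appearing as sustained shifts in residual
  mean/variance, located by exact changepoint segmentation at level
  ``alpha_changepoint`` (default 0.05).

Session indices are 1-based throughout, matching milking-session numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._changepoint import meanvar_penalty, pelt_meanvar

__all__ = [
    "ConditionalElements",
    "detect_extreme_retention",
    "detect_beta_segments",
    "discover",
]


@dataclass
class ConditionalElements:
    """Discovered conditional elements of one lactation."""

    extreme_sessions: set = field(default_factory=set)
    segment_starts: tuple = (1,)

    @property
    def n_segments(self) -> int:
        return len(self.segment_starts)

    def to_dict(self) -> dict:
        return {
            "extreme_sessions": sorted(int(k) for k in self.extreme_sessions),
            "segment_starts": [int(s) for s in self.segment_starts],
            "n_segments": self.n_segments,
        }


def detect_extreme_retention(std_residuals, alpha: float = 0.001) -> set:
    """Sessions with extreme retention, as 1-based indices.

    A session is a candidate when its standardized residual has two-sided
    normal tail probability below ``alpha``.  A *positive* candidate
    immediately following a negative candidate is interpreted as the
    carryover rebound of the preceding high-retention session (the milk
    retained at k is extracted at k+1) and is not flagged itself.
    """
    z = np.asarray(std_residuals, dtype=float)
    if z.size == 0:
        raise ValueError("empty residual vector")
    thr = stats.norm.isf(alpha / 2.0)
    cand = np.flatnonzero(np.abs(z) > thr)
    cand_set = set(cand.tolist())
    flagged = set()
    for i in cand:
        if z[i] > 0 and (i - 1) in cand_set and z[i - 1] < 0:
            continue  # rebound from retention at the previous session
        flagged.add(int(i) + 1)
    return flagged


def detect_beta_segments(
    std_residuals,
    alpha: float = 0.05,
    min_segment_length: int = 30,
    exclude_sessions=(),
):
    """Interval indices (1-based) opening each secretion-rate segment.

    ``exclude_sessions`` (1-based, typically the extreme-retention flags
    and their rebound successors) are removed before segmentation to avoid
    masking; detected boundaries are mapped back to original indices.
    """
    z = np.asarray(std_residuals, dtype=float)
    n = len(z)
    if n == 0:
        raise ValueError("empty residual vector")
    keep = np.setdiff1d(np.arange(n), np.asarray(sorted(exclude_sessions), dtype=int) - 1)
    zk = z[keep]
    if len(zk) < 2 * min_segment_length:
        return (1,)
    pen = meanvar_penalty(len(zk), alpha)
    starts_reduced = pelt_meanvar(zk, penalty=pen, min_size=min_segment_length)
    starts = tuple(int(keep[s]) + 1 for s in starts_reduced)
    return starts if starts and starts[0] == 1 else (1,) + starts


def discover(
    std_residuals,
    alpha_extreme: float = 0.001,
    alpha_changepoint: float = 0.05,
    min_segment_length: int = 30,
) -> ConditionalElements:
    """Run both detectors on stage-1 residuals.

    The changepoint input excludes flagged extreme sessions and their
    immediate successors (both are perturbed by an extreme retention).
    """
    flagged = detect_extreme_retention(std_residuals, alpha_extreme)
    exclude = set(flagged) | {k + 1 for k in flagged}
    starts = detect_beta_segments(
        std_residuals,
        alpha=alpha_changepoint,
        min_segment_length=min_segment_length,
        exclude_sessions=exclude,
    )
    return ConditionalElements(extreme_sessions=flagged, segment_starts=starts)
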