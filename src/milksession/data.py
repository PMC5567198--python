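"""Observed-lactation container shared by I/O, estimation and simulation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import MilkingSchedule

__all__ = ["LactationSeries"]


@dataclass
class LactationSeries:
    """One lactation of per-session milking records.

    Attributes
    ----------
    hours : np.ndarray
        Session times in hours since the *first* session (hours[0] = 0).
        The model time t(k) = delta + hours[k] is formed at fit time.
    yields_kg : np.ndarray
        Observed (measured) udder-total yield per session, kg.
    labels : np.ndarray
        'M' / 'E' per session (morning = preceded by the long overnight
        interval).
    datetimes : optional pandas.DatetimeIndex-compatible array
        Original timestamps when read from file.
    truth : dict
        Ground-truth sidecar populated by the simulator (empty for real
        data).
    """

    hours: np.ndarray
    yields_kg: np.ndarray
    labels: np.ndarray
    datetimes: Optional[object] = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.hours = np.asarray(self.hours, dtype=float)
        self.yields_kg = np.asarray(self.yields_kg, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U1")
        if not (len(self.hours) == len(self.yields_kg) == len(self.labels)):
            raise ValueError("hours, yields_kg and labels must align")
        if len(self.hours) == 0:
            raise ValueError("empty series")
        if self.hours[0] != 0.0:
            raise ValueError("hours must be relative to the first session (hours[0]=0)")
        if np.any(np.diff(self.hours) <= 0):
            raise ValueError("session times must be strictly increasing")
        if np.any(self.yields_kg < 0):
            raise ValueError("yields must be >= 0")

    def __len__(self) -> int:
        return len(self.hours)

    @property
    def n_sessions(self) -> int:
        return len(self.hours)

    def schedule(self, delta: float) -> MilkingSchedule:
        """Model schedule for a candidate lactation-onset offset ``delta``."""
        return MilkingSchedule.from_hours_since_first(self.hours, self.labels, delta)

    def nominal_schedule(self, delta: float, nominal_deltas=(14.0, 10.0)) -> MilkingSchedule:
        """Schedule-only mode: rebuild times from the nominal interval
        lengths implied by the session labels (14 h before a morning
        session, 10 h before an evening one), ignoring ``hours``."""
        dts = np.where(self.labels == "M", nominal_deltas[0], nominal_deltas[1])
        dts[0] = 0.0
        hours = np.cumsum(dts)
        return MilkingSchedule.from_hours_since_first(hours, self.labels, delta)

    @property
    def day_index(self) -> np.ndarray:
        """Calendar-day index per session (0-based).

        Uses the stored timestamps' dates when available, else whole days
        elapsed since the first session.
        """
        if self.datetimes is not None:
            import pandas as pd

            d = pd.DatetimeIndex(self.datetimes)
            return (d.normalize() - d[0].normalize()).days.to_numpy()
        return (self.hours // 24).astype(int)
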