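"""Reading and writing per-session milking records and fit reports.

The session CSV dialect has columns ``session_id, datetime, q1..q4`` (or a
single ``total_kg``) and an optional ``label`` ('M'/'E').  Quarter yields
are summed to the udder total — the model works on whole-udder milk.
Timestamps are converted to fractional hours of exact elapsed time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LactationSeries

__all__ = ["read_sessions", "write_sessions", "write_fit_report", "write_residuals"]

_QUARTER_COLS = ["q1", "q2", "q3", "q4"]


def read_sessions(path, label_noon_rule: bool = True) -> LactationSeries:
    """Load a lactation from a session CSV.

    Yields come from ``total_kg`` or the sum of ``q1..q4`` (both present:
    they must agree to 1e-6 kg).  Labels default to the clock-time rule
    (before noon = morning) when no ``label`` column exists.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    if "datetime" not in cols:
        raise ValueError(f"{path}: missing required column 'datetime'")
    has_q = all(c in cols for c in _QUARTER_COLS)
    if not has_q and "total_kg" not in cols:
        raise ValueError(f"{path}: need columns q1..q4 or total_kg")

    dt = pd.to_datetime(df["datetime"], format="ISO8601")
    for i in range(1, len(dt)):
        if dt.iloc[i] <= dt.iloc[i - 1]:
            raise ValueError(
                f"{path}, line {i + 2}: non-increasing timestamp {dt.iloc[i]}"
            )
    if has_q:
        q = df[_QUARTER_COLS].to_numpy(dtype=float)
        if np.any(q < 0):
            bad = int(np.argwhere(q < 0)[0][0])
            raise ValueError(f"{path}, line {bad + 2}: negative quarter yield")
        total = q.sum(axis=1)
        if "total_kg" in cols:
            declared = df["total_kg"].to_numpy(dtype=float)
            off = np.abs(declared - total) > 1e-6
            if np.any(off):
                bad = int(np.argmax(off))
                raise ValueError(
                    f"{path}, line {bad + 2}: total_kg disagrees with quarter sum"
                )
    else:
        total = df["total_kg"].to_numpy(dtype=float)
    if np.any(total < 0):
        bad = int(np.argmax(total < 0))
        raise ValueError(f"{path}, line {bad + 2}: negative yield")

    hours = (dt - dt.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    if "label" in cols:
        labels = df["label"].astype(str).str.upper().str[0].to_numpy()
        if not set(labels) <= {"M", "E"}:
            raise ValueError(f"{path}: labels must be 'M' or 'E'")
    elif label_noon_rule:
        labels = np.where(dt.dt.hour < 12, "M", "E")
    else:
        raise ValueError(f"{path}: no label column and labelling disabled")
    return LactationSeries(
        hours=hours, yields_kg=total, labels=labels, datetimes=dt.to_numpy()
    )


def write_sessions(series: LactationSeries, path, start="2016-01-01 06:00:00") -> None:
    """Write a lactation in the session CSV dialect (lossless round trip
    of times to the second, yields to full float precision)."""
    path = Path(path)
    if series.datetimes is not None:
        dt = pd.DatetimeIndex(series.datetimes)
    else:
        dt = pd.Timestamp(start) + pd.to_timedelta(
            np.round(series.hours * 3600.0), unit="s"
        )
    df = pd.DataFrame(
        {
            "session_id": np.arange(1, len(series) + 1),
            "datetime": pd.DatetimeIndex(dt).strftime("%Y-%m-%dT%H:%M:%S"),
            "total_kg": np.asarray(series.yields_kg, dtype=float),
            "label": series.labels,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_fit_report(result, path, elements=None, extra=None) -> None:
    """Fit results (estimates, CIs, likelihood, convergence) as JSON."""
    payload = result.summary_dict()
    if elements is not None:
        payload["conditional_elements"] = elements.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_residuals(result, series: LactationSeries, path) -> None:
    """Per-session observed/fitted/residual table as CSV."""
    pd.DataFrame(
        {
            "k": np.arange(1, len(series) + 1),
            "hours_since_first": series.hours,
            "label": series.labels,
            "observed_kg": series.yields_kg,
            "fitted_kg": result.fitted_mean,
            "model_var": result.fitted_var,
            "std_residual": result.std_residuals,
        }
    ).to_csv(path, index=False, float_format="%.10g")
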