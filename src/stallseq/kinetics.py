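"""Ribosome transit-time estimation from luminescence traces.

In a continuous in vitro translation assay, luminescence stays near zero
until the first ribosomes traverse the full transcript, then rises linearly
as completed reporters accumulate.  The transit time is the X-intercept of a
straight-line fit to the linear regime; replicate traces give its SEM.  The
fit window is user-supplied (chosen per construct by inspecting the linear
regime); an optional automatic mode picks the sliding window maximizing R².
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class TransitFit:
    """Linear-regime fit and the X-intercept transit time."""

    fit_window: tuple[float, float]  # seconds
    slope: float  # signal units per second, mean over replicates
    transit_time_s: float  # mean X-intercept over replicates
    sem_s: float  # SEM over replicates (0 for a single replicate)
    per_replicate: list[float]


def _fit_one(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line; returns (slope, x_intercept)."""
    slope, intercept = np.polyfit(t, y, 1)
    if slope <= 0:
        raise ValueError(f"non-positive slope {slope:.4g}; no linear rise in window")
    return float(slope), float(-intercept / slope)


def fit_transit_time(
    traces: Sequence[pd.DataFrame] | pd.DataFrame,
    window: tuple[float, float],
) -> TransitFit:
    """Transit time from replicate luminescence traces.

    ``traces`` is a list of DataFrames with columns (time_s, signal), or one
    DataFrame with a ``replicate_id`` column.  Each replicate is fit with a
    least-squares line over points with t_start < t < t_end; the transit time
    is −intercept/slope, reported as mean ± SEM over replicates.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t_start < t_end")
    if isinstance(traces, pd.DataFrame):
        if "replicate_id" in traces.columns:
            traces = [g for _, g in traces.groupby("replicate_id", sort=True)]
        else:
            traces = [traces]
    slopes, intercepts = [], []
    for trace in traces:
        t = trace["time_s"].to_numpy(float)
        y = trace["signal"].to_numpy(float)
        if t0 < t.min() or t1 > t.max():
            raise ValueError(f"window ({t0}, {t1}) outside trace span ({t.min()}, {t.max()})")
        mask = (t > t0) & (t < t1)
        if mask.sum() < 3:
            raise ValueError("need at least 3 points inside the fit window")
        slope, x_int = _fit_one(t[mask], y[mask])
        slopes.append(slope)
        intercepts.append(x_int)
    n = len(intercepts)
    sem = float(np.std(intercepts, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return TransitFit(
        fit_window=(t0, t1),
        slope=float(np.mean(slopes)),
        transit_time_s=float(np.mean(intercepts)),
        sem_s=sem,
        per_replicate=[float(x) for x in intercepts],
    )


def auto_window(
    trace: pd.DataFrame,
    width_s: float = 300.0,
    step_s: float = 50.0,
) -> tuple[float, float]:
    """Sliding window of fixed width maximizing linear-fit R².

    A convenience for exploratory use; the reported analyses use explicit
    per-construct windows.  Windows with a non-positive slope are skipped.
    """
    t = trace["time_s"].to_numpy(float)
    y = trace["signal"].to_numpy(float)
    best: tuple[float, tuple[float, float]] | None = None
    start = t.min()
    while start + width_s <= t.max():
        mask = (t > start) & (t < start + width_s)
        if mask.sum() >= 3:
            slope, intercept = np.polyfit(t[mask], y[mask], 1)
            if slope > 0:
                pred = slope * t[mask] + intercept
                ss_res = float(((y[mask] - pred) ** 2).sum())
                ss_tot = float(((y[mask] - y[mask].mean()) ** 2).sum())
                r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
                if best is None or r2 > best[0]:
                    best = (r2, (start, start + width_s))
        start += step_s
    if best is None:
        raise ValueError("no window with a positive slope found")
    return best[1]


def read_traces_tsv(path: str | Path) -> list[pd.DataFrame]:
    """Read replicate traces from TSV columns (time_s, replicate_id, signal)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"time_s", "replicate_id", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"trace TSV missing columns: {sorted(missing)}")
    return [g.sort_values("time_s") for _, g in df.groupby("replicate_id", sort=True)]
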