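"""Extreme-event detection on daily series against a percentile climatology.

Marine heatwaves (MHW) and cold-spells (MCS) are maximal runs of days on which
SST exceeds (falls below) a day-of-year percentile threshold for at least a
minimum duration; high/low chlorophyll-a extremes (HChl-a/LChl-a) are the same
construction on Chl-a series with a shorter minimum duration. Qualifying runs
separated by at most ``max_gap`` non-exceedant days are joined into a single
event (the Hobday convention: filter runs by duration first, then merge).

Intensities are departures from the climatological *mean* (not the threshold):
max intensity is the most extreme signed departure in the span, mean and
cumulative intensity average/sum the departure over all span days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .climatology import Climatology, as_daily_series, day_of_year_365

__all__ = [
    "DetectionParams",
    "ExtremeEvent",
    "SST_TREND_PARAMS",
    "SST_COMPOUND_PARAMS",
    "CHLA_PARAMS",
    "duration_days",
    "detect_events",
    "event_metrics",
    "events_to_frame",
]

Polarity = Literal["high", "low"]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds and run rules for one detection pass.

    ``upper_percentile``/``lower_percentile`` select the climatology curves
    used for high/low polarity. ``comparison`` is "strict" (value > threshold,
    the default reading of "exceeded") or "inclusive" (>=).
    """

    upper_percentile: float = 90.0
    lower_percentile: float = 10.0
    min_duration: int = 5
    max_gap: int = 2
    comparison: str = "strict"

    def __post_init__(self):
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.comparison not in ("strict", "inclusive"):
            raise ValueError(f"comparison must be strict|inclusive, got {self.comparison!r}")


#: SST settings for decadal trend analysis: 90th/10th percentile, >= 5 days.
SST_TREND_PARAMS = DetectionParams(90.0, 10.0, min_duration=5, max_gap=2)
#: Stricter SST settings for compound-event analysis: 92nd/8th, >= 10 days.
SST_COMPOUND_PARAMS = DetectionParams(92.0, 8.0, min_duration=10, max_gap=2)
#: Chlorophyll-a settings: 90th/10th percentile, >= 3 days, no gap joining.
CHLA_PARAMS = DetectionParams(90.0, 10.0, min_duration=3, max_gap=0)


@dataclass(frozen=True)
class ExtremeEvent:
    """One detected episode, dates inclusive at both ends."""

    variable: str
    polarity: Polarity
    start: pd.Timestamp
    end: pd.Timestamp
    duration: int
    max_intensity: float
    mean_intensity: float
    cumulative_intensity: float
    peak_date: pd.Timestamp
    n_missing: int = 0
    edge_truncated: bool = False

    def overlaps(self, start, end) -> bool:
        """True if the event span shares at least one day with [start, end]."""
        return self.start <= pd.Timestamp(end) and self.end >= pd.Timestamp(start)


def duration_days(start_date, end_date) -> int:
    """Inclusive day count of a date span (leap-year aware)."""
    start, end = pd.Timestamp(start_date), pd.Timestamp(end_date)
    if start > end:
        raise ValueError(f"reversed span: {start.date()} > {end.date()}")
    return int((end - start).days) + 1


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, end) inclusive index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def event_metrics(
    series: pd.Series,
    clim: Climatology,
    span: tuple,
    polarity: Polarity,
) -> dict:
    """Intensity metrics over a date span.

    Departures are value minus climatological mean per day. Missing days are
    excluded from the statistics and counted in ``n_missing``.
    """
    s = as_daily_series(series)
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if start < s.index[0] or end > s.index[-1]:
        raise ValueError(f"span {start.date()}..{end.date()} outside series")
    chunk = s.loc[start:end]
    intensity = chunk.to_numpy() - clim.clim_mean[day_of_year_365(chunk.index) - 1]
    ok = ~np.isnan(intensity)
    if not ok.any():
        raise ValueError(f"span {start.date()}..{end.date()} has no non-missing values")
    vals = intensity[ok]
    dates = chunk.index[ok]
    peak_i = int(np.argmax(vals)) if polarity == "high" else int(np.argmin(vals))
    return {
        "max_intensity": float(vals[peak_i]),
        "mean_intensity": float(vals.mean()),
        "cumulative_intensity": float(vals.sum()),
        "peak_date": dates[peak_i],
        "n_missing": int((~ok).sum()),
    }


def detect_events(
    series: pd.Series,
    clim: Climatology,
    params: DetectionParams = SST_TREND_PARAMS,
    variable: str = "sst",
    polarity: str = "both",
) -> list[ExtremeEvent]:
    """Detect high and/or low extremes in a daily series.

    Missing days never exceed a threshold, so they break runs (Chl-a callers
    are expected to pass the gap-interpolated series from preprocessing).
    Returns events in chronological order; high and low events cannot overlap
    because a day exceeds at most one of the two thresholds.
    """
    if polarity not in ("high", "low", "both"):
        raise ValueError(f"polarity must be high|low|both, got {polarity!r}")
    if clim.variable and variable and clim.variable != variable:
        raise ValueError(
            f"series variable {variable!r} does not match climatology {clim.variable!r}"
        )
    s = as_daily_series(series)
    values = s.to_numpy()
    events: list[ExtremeEvent] = []
    wanted: Sequence[Polarity] = ("high", "low") if polarity == "both" else (polarity,)
    for pol in wanted:
        pct = params.upper_percentile if pol == "high" else params.lower_percentile
        thr = clim.threshold(pct, s.index)
        with np.errstate(invalid="ignore"):
            if params.comparison == "strict":
                mask = (values > thr) if pol == "high" else (values < thr)
            else:
                mask = (values >= thr) if pol == "high" else (values <= thr)
        mask &= ~np.isnan(values)
        runs = [r for r in _runs(mask) if r[1] - r[0] + 1 >= params.min_duration]
        merged: list[tuple[int, int]] = []
        for run in runs:
            if merged and run[0] - merged[-1][1] - 1 <= params.max_gap:
                merged[-1] = (merged[-1][0], run[1])
            else:
                merged.append(run)
        for i0, i1 in merged:
            start, end = s.index[i0], s.index[i1]
            m = event_metrics(s, clim, (start, end), pol)
            events.append(
                ExtremeEvent(
                    variable=variable,
                    polarity=pol,
                    start=start,
                    end=end,
                    duration=duration_days(start, end),
                    edge_truncated=(i0 == 0 or i1 == len(s) - 1),
                    **m,
                )
            )
    events.sort(key=lambda e: (e.start, e.polarity))
    return events


def events_to_frame(events: Sequence[ExtremeEvent]) -> pd.DataFrame:
    """Event table: one row per event, CSV-friendly."""
    rows = [
        {
            "variable": e.variable,
            "polarity": e.polarity,
            "start": e.start.date().isoformat(),
            "end": e.end.date().isoformat(),
            "duration_days": e.duration,
            "max_intensity": e.max_intensity,
            "mean_intensity": e.mean_intensity,
            "cumulative_intensity": e.cumulative_intensity,
            "peak_date": e.peak_date.date().isoformat(),
            "n_missing": e.n_missing,
            "edge_truncated": e.edge_truncated,
        }
        for e in events
    ]
    columns = [
        "variable", "polarity", "start", "end", "duration_days", "max_intensity",
        "mean_intensity", "cumulative_intensity", "peak_date", "n_missing",
        "edge_truncated",
    ]
    return pd.DataFrame(rows, columns=columns)
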