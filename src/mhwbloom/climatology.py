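"""Day-of-year climatologies: windowed percentile thresholds, means and dispersion.

A climatology summarises a daily series into 365 calendar-day slots. For each
slot, all observations within a centred window (default 11 days: the slot day
plus/minus 5) across every reference year are pooled; the slot mean, requested
percentiles and standard deviation are computed on that pool, and each of the
resulting annual curves is then smoothed with a centred circular moving mean
(default 31 days). This is the standard construction used for marine heatwave
threshold climatologies, applied identically to SST (degC) and chlorophyll-a
(mg/m3) series.

Leap days carry no slot of their own: 29 February contributes to, and reads
from, the 28 February slot, so every year maps onto the same 365 slots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Climatology",
    "as_daily_series",
    "day_of_year_365",
    "build_climatology",
    "climatology_at",
    "standardized_anomaly",
    "anomaly",
]


def as_daily_series(series: pd.Series) -> pd.Series:
    """Coerce a date-indexed series to strict daily cadence.

    The index must be datetime-like with no duplicate dates. Calendar gaps are
    re-introduced as missing values (NaN), so absence and missingness are the
    same thing downstream.
    """
    if not isinstance(series, pd.Series):
        raise TypeError("expected a pandas Series with a datetime index")
    idx = pd.DatetimeIndex(series.index)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicate date in series: {dup.date()}")
    s = pd.Series(np.asarray(series, dtype=float), index=idx).sort_index()
    full = pd.date_range(s.index[0], s.index[-1], freq="D")
    return s.reindex(full)


def day_of_year_365(index: pd.DatetimeIndex) -> np.ndarray:
    """Map dates to 1..365 calendar-day slots; 29 Feb shares slot 59 (28 Feb)."""
    idx = pd.DatetimeIndex(index)
    doy = idx.dayofyear.to_numpy().copy()
    # in leap years every day from 29 Feb (doy 60) onwards shifts down by one
    doy[idx.is_leap_year & (doy > 59)] -= 1
    return doy


def _circular_moving_mean(values: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return values.astype(float)
    if window % 2 == 0:
        raise ValueError(f"smooth_window must be odd, got {window}")
    half = window // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    # sliding mean (not a convolution kernel) so constant input stays exact
    return np.lib.stride_tricks.sliding_window_view(padded, window).mean(axis=1)


@dataclass(frozen=True)
class Climatology:
    """Per-calendar-day statistics with their construction parameters.

    ``clim_mean``, ``clim_sd`` and each entry of ``thresholds`` are arrays of
    length 365 indexed by slot (0-based; slot ``d`` holds calendar day
    ``d + 1``).
    """

    clim_mean: np.ndarray
    clim_sd: np.ndarray
    thresholds: Mapping[float, np.ndarray]
    window_halfwidth: int
    smooth_window: int
    reference_period: tuple[int, int]
    variable: str = ""
    percentile_method: str = "linear"

    def threshold(self, percentile: float, dates: pd.DatetimeIndex) -> np.ndarray:
        """Threshold values of ``percentile`` for each date."""
        if percentile not in self.thresholds:
            raise KeyError(
                f"climatology has no {percentile} percentile "
                f"(available: {sorted(self.thresholds)})"
            )
        return self.thresholds[percentile][day_of_year_365(dates) - 1]

    def mean_at(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.clim_mean[day_of_year_365(dates) - 1]

    def sd_at(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.clim_sd[day_of_year_365(dates) - 1]

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one row per slot, one column per statistic."""
        data = {"slot": np.arange(1, 366), "mean": self.clim_mean, "sd": self.clim_sd}
        for p in sorted(self.thresholds):
            data[f"p{p:g}"] = self.thresholds[p]
        return pd.DataFrame(data).set_index("slot")


def build_climatology(
    series: pd.Series,
    reference_period: tuple[int, int],
    percentiles: Sequence[float] = (10.0, 90.0),
    window_halfwidth: int = 5,
    smooth_window: int = 31,
    percentile_method: str = "linear",
    variable: str = "",
) -> Climatology:
    """Build a day-of-year climatology from a daily series.

    Parameters
    ----------
    series
        Daily series; missing values are dropped from the pools.
    reference_period
        ``(first_year, last_year)`` inclusive; the series must cover at least
        one full calendar year inside it.
    percentiles
        Percentile thresholds to compute, in (0, 100).
    window_halfwidth
        Pooling half-window in days (5 gives the standard 11-day window).
    smooth_window
        Width of the centred circular moving-mean smoother (odd, in days)
        applied to the mean, the dispersion and every threshold curve.
    percentile_method
        Quantile interpolation rule handed to :func:`numpy.percentile`.
    """
    s = as_daily_series(series)
    y0, y1 = int(reference_period[0]), int(reference_period[1])
    if y0 > y1:
        raise ValueError(f"reference_period reversed: {reference_period}")
    ref = s.loc[f"{y0}-01-01": f"{y1}-12-31"]
    if ref.empty:
        raise ValueError(
            f"reference period {y0}-{y1} lies outside the series span "
            f"{s.index[0].date()}..{s.index[-1].date()}"
        )
    full_years = [
        y for y in range(y0, y1 + 1)
        if s.index[0] <= pd.Timestamp(y, 1, 1) and pd.Timestamp(y, 12, 31) <= s.index[-1]
    ]
    if not full_years:
        raise ValueError(
            f"series does not cover one full year inside reference period {y0}-{y1}"
        )
    for p in percentiles:
        if not 0.0 < float(p) < 100.0:
            raise ValueError(f"percentile out of (0, 100): {p}")
    if window_halfwidth < 0:
        raise ValueError("window_halfwidth must be >= 0")

    slots = day_of_year_365(ref.index) - 1
    values = ref.to_numpy()
    valid = ~np.isnan(values)
    # group observations by slot once, then pool neighbouring slots per day
    order = np.argsort(slots[valid], kind="stable")
    sorted_vals = values[valid][order]
    counts = np.bincount(slots[valid], minlength=365)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    by_slot = [sorted_vals[bounds[d]: bounds[d + 1]] for d in range(365)]

    qs = sorted(float(p) for p in percentiles)
    mean = np.empty(365)
    sd = np.empty(365)
    thr = {p: np.empty(365) for p in qs}
    offsets = range(-window_halfwidth, window_halfwidth + 1)
    for d in range(365):
        pool = np.concatenate([by_slot[(d + off) % 365] for off in offsets])
        if pool.size == 0:
            raise ValueError(f"empty climatology pool for calendar-day slot {d + 1}")
        mean[d] = pool.mean()
        sd[d] = pool.std(ddof=1) if pool.size > 1 else 0.0
        if qs:
            vals = np.percentile(pool, qs, method=percentile_method)
            for p, v in zip(qs, vals):
                thr[p][d] = v

    mean = _circular_moving_mean(mean, smooth_window)
    sd = _circular_moving_mean(sd, smooth_window)
    thr = {p: _circular_moving_mean(v, smooth_window) for p, v in thr.items()}
    return Climatology(
        clim_mean=mean,
        clim_sd=sd,
        thresholds=thr,
        window_halfwidth=window_halfwidth,
        smooth_window=smooth_window,
        reference_period=(y0, y1),
        variable=variable,
        percentile_method=percentile_method,
    )


def climatology_at(clim: Climatology, date) -> tuple[float, dict[float, float], float]:
    """Slot values (mean, thresholds, sd) for a single date.

    29 February reads from the 28 February slot; values are year-invariant.
    """
    idx = pd.DatetimeIndex([pd.Timestamp(date)])
    slot = day_of_year_365(idx)[0] - 1
    return (
        float(clim.clim_mean[slot]),
        {p: float(v[slot]) for p, v in clim.thresholds.items()},
        float(clim.clim_sd[slot]),
    )


def anomaly(series: pd.Series, clim: Climatology) -> pd.Series:
    """Per-date departure from the climatological mean; missing in, missing out."""
    s = as_daily_series(series)
    return s - clim.mean_at(s.index)


def standardized_anomaly(series: pd.Series, clim: Climatology) -> pd.Series:
    """(value - clim_mean) / clim_sd per date.

    Raises if any date carrying a non-missing value falls on a slot with zero
    climatological dispersion.
    """
    s = as_daily_series(series)
    slots = day_of_year_365(s.index) - 1
    sd = clim.clim_sd[slots]
    touched = ~np.isnan(s.to_numpy())
    bad = touched & (sd == 0.0)
    if bad.any():
        slot = int(slots[np.argmax(bad)]) + 1
        raise ValueError(f"zero climatological standard deviation on slot {slot}")
    return (s - clim.clim_mean[slots]) / sd
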