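"""Decadal trends in extreme-event days.

Annual event-day counts (days inside detected events falling within a
season's blooming window) are regressed on the season year by ordinary least
squares; the slope is reported per decade and its significance comes from the
two-sided t test on the slope with n - 2 degrees of freedom. No serial-
correlation correction is applied to the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .compound import BloomingPeriod, resolve_period
from .events import ExtremeEvent

__all__ = [
    "TrendResult",
    "seasonal_event_days",
    "decadal_trend",
    "trend_map",
]


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of annual event days.

    ``slope`` is in event-days per decade (10x the per-year slope);
    ``stderr`` is the slope standard error on the same scale. ``degenerate``
    flags zero-residual fits (e.g. a constant series), for which the t
    statistic is undefined and p is reported as 1.
    """

    slope: float
    intercept: float
    p_value: float
    significant: bool
    alpha: float
    n_years: int
    stderr: float
    degenerate: bool = False

    def ci95(self) -> tuple[float, float]:
        """95% confidence interval of the decadal slope."""
        if self.degenerate or self.n_years < 3:
            return (self.slope, self.slope)
        t = stats.t.ppf(0.975, self.n_years - 2)
        return (self.slope - t * self.stderr, self.slope + t * self.stderr)


def seasonal_event_days(
    events: Sequence[ExtremeEvent],
    window: BloomingPeriod,
    season_year: int,
    data_span: tuple | None = None,
) -> int:
    """Total event days inside the resolved window for one season.

    Days of an overlapping event that fall outside the window are not
    counted. ``data_span`` (start, end), when given, must contain the window.
    """
    start, end = resolve_period(window, season_year)
    if data_span is not None:
        d0, d1 = pd.Timestamp(data_span[0]), pd.Timestamp(data_span[1])
        if start < d0 or end > d1:
            raise ValueError(
                f"window {start.date()}..{end.date()} outside data span "
                f"{d0.date()}..{d1.date()}"
            )
    total = 0
    for e in events:
        lo = max(e.start, start)
        hi = min(e.end, end)
        if lo <= hi:
            total += (hi - lo).days + 1
    return total


def _as_year_value_arrays(annual_days) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(annual_days, pd.Series):
        years = np.asarray(annual_days.index, dtype=float)
        vals = annual_days.to_numpy(dtype=float)
    elif isinstance(annual_days, Mapping):
        years = np.asarray(sorted(annual_days), dtype=float)
        vals = np.asarray([annual_days[y] for y in sorted(annual_days)], dtype=float)
    else:
        pairs = list(annual_days)
        years = np.asarray([p[0] for p in pairs], dtype=float)
        vals = np.asarray([p[1] for p in pairs], dtype=float)
    return years, vals


def decadal_trend(annual_days, alpha: float = 0.05) -> TrendResult:
    """OLS linear trend of annual event days, in days per decade.

    ``annual_days`` is a sequence of (season_year, days) pairs, a mapping, or
    a year-indexed Series. Requires at least 3 finite points with non-constant
    years. A perfectly fitting (zero-residual) regression has an undefined t
    statistic; it is returned with p = 1 and ``degenerate=True`` rather than
    raising, because trend maps routinely contain flat pixels.
    """
    years, vals = _as_year_value_arrays(annual_days)
    ok = np.isfinite(vals) & np.isfinite(years)
    years, vals = years[ok], vals[ok]
    n = len(vals)
    if n < 3:
        raise ValueError(f"need >= 3 finite annual values, got {n}")
    if np.ptp(years) == 0:
        raise ValueError("zero variance in years")

    x = years - years.mean()
    sxx = float(np.sum(x * x))
    slope_yr = float(np.sum(x * vals) / sxx)
    intercept = float(vals.mean() - slope_yr * years.mean())
    resid = vals - (intercept + slope_yr * years)
    ss_res = float(np.sum(resid**2))
    dof = n - 2
    s2 = ss_res / dof
    stderr_yr = float(np.sqrt(s2 / sxx))
    if stderr_yr == 0.0:
        return TrendResult(
            slope=slope_yr * 10.0,
            intercept=intercept,
            p_value=1.0,
            significant=False,
            alpha=alpha,
            n_years=n,
            stderr=0.0,
            degenerate=True,
        )
    t = slope_yr / stderr_yr
    p = 2.0 * stats.t.sf(abs(t), dof)
    return TrendResult(
        slope=slope_yr * 10.0,
        intercept=intercept,
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
        n_years=n,
        stderr=stderr_yr * 10.0,
    )


def trend_map(annual_day_fields: xr.DataArray, alpha: float = 0.05) -> xr.Dataset:
    """Per-pixel decadal trends from gridded annual event-day counts.

    ``annual_day_fields`` must have a ``season_year`` dimension plus any
    number of spatial dimensions. Pixels with fewer than 3 finite years
    propagate missing values.
    """
    if "season_year" not in annual_day_fields.dims:
        raise ValueError("input needs a 'season_year' dimension")
    years = annual_day_fields["season_year"].to_numpy()
    slope, p, sig = _trend_map_loop(annual_day_fields, years, alpha)
    ds = xr.Dataset({"slope": slope, "p_value": p, "significant": sig})
    ds["slope"].attrs["units"] = "event-days per decade"
    ds["significant"].attrs["note"] = f"p < {alpha}; NaN where trend undefined"
    return ds


def _trend_map_loop(da: xr.DataArray, years: np.ndarray, alpha: float):
    stacked = da.transpose(..., "season_year")
    spatial_dims = [d for d in stacked.dims if d != "season_year"]
    arr = stacked.to_numpy()
    shape = arr.shape[:-1]
    slope = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    sig = np.full(shape, np.nan)
    for idx in np.ndindex(shape):
        col = arr[idx]
        ok = np.isfinite(col)
        if ok.sum() < 3 or np.ptp(years[ok]) == 0:
            continue
        r = decadal_trend(list(zip(years[ok], col[ok])), alpha=alpha)
        slope[idx] = r.slope
        p[idx] = r.p_value
        sig[idx] = float(r.significant)
    coords = {d: stacked.coords[d] for d in spatial_dims if d in stacked.coords}
    mk = lambda a: xr.DataArray(a, dims=spatial_dims, coords=coords)
    return mk(slope), mk(p), mk(sig)
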