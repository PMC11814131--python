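"""Synthetic daily SST / chlorophyll-a series, gridded fields and profiles.

Every downstream stage (climatology, detection, compound matching, trends,
MLD) is exercised against data from this module, so each generator records
its ground truth. The statistical structure emulates what multi-decadal
satellite series look like in a warm oligotrophic basin:

* SST: a smooth seasonal cycle plus an optional linear warming trend plus
  AR(1) Gaussian residuals (``noise_sd`` is the stationary standard
  deviation, ``ar1_coef`` the lag-1 autocorrelation), with injected warm or
  cold episodes added as a constant offset over their span.
* Chl-a: a positive seasonal winter-bloom curve with multiplicative
  lognormal noise (mean-corrected, so the expected value equals the bloom
  curve), random missing days, occasional spurious spikes above 10 mg/m3
  (to exercise quality control), and a lagged multiplicative response to the
  injected SST episodes — warm events depress Chl-a, cold events elevate it,
  the hypothesised open-water coupling.
* Profiles: an isothermal mixed layer over a linear thermocline, with an
  optional cool subsurface intrusion layer.

The injected coupling acts on the mean level (additively in log space), not
on the noise, so expected responses are analytically checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "InjectedEvent",
    "ScenarioConfig",
    "SyntheticTruth",
    "generate_sst",
    "generate_chla",
    "generate_profile",
    "generate_sst_field",
    "generate_chla_field",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class InjectedEvent:
    """One prescribed warm or cold episode with its Chl-a response.

    ``amplitude`` (degC, positive) is added to SST for warm events and
    subtracted for cold ones over the inclusive span. The Chl-a response is a
    multiplicative factor ``chla_response_amp`` applied to the bloom curve
    over the same span shifted by the scenario's coupling lag; its direction
    must agree with ``chla_response_sign`` (-1 depress, +1 elevate, 0 none).
    Left unset, the response follows the expected pattern: warm -> depressed
    (factor 0.5), cold -> elevated (factor 2.0).
    """

    polarity: str
    start_date: str | pd.Timestamp
    duration: int
    amplitude: float
    chla_response_sign: int | None = None
    chla_response_amp: float | None = None

    def __post_init__(self):
        if self.polarity not in ("warm", "cold"):
            raise ValueError(f"polarity must be warm|cold, got {self.polarity!r}")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        sign = self.chla_response_sign
        if sign is None:
            sign = -1 if self.polarity == "warm" else 1
        if sign not in (-1, 0, 1):
            raise ValueError("chla_response_sign must be -1, 0 or +1")
        amp = self.chla_response_amp
        if amp is None:
            amp = {-1: 0.5, 0: 1.0, 1: 2.0}[sign]
        if amp <= 0:
            raise ValueError("chla_response_amp must be > 0")
        if sign == -1 and amp >= 1:
            raise ValueError("depressing response (sign -1) needs chla_response_amp < 1")
        if sign == 1 and amp <= 1:
            raise ValueError("elevating response (sign +1) needs chla_response_amp > 1")
        object.__setattr__(self, "chla_response_sign", sign)
        object.__setattr__(self, "chla_response_amp", amp)
        object.__setattr__(self, "start_date", pd.Timestamp(self.start_date))

    @property
    def end_date(self) -> pd.Timestamp:
        return self.start_date + pd.Timedelta(days=self.duration - 1)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults describe a 21-year record (1998-2018) of a warm oligotrophic
    basin: seasonal SST 24-30 degC peaking in mid-August, moderately
    persistent residuals (lag-1 autocorrelation 0.7, stationary sd 0.5 degC),
    and a winter Chl-a bloom rising from a 0.15 mg/m3 background to about
    0.5 mg/m3 around early February with 30% multiplicative noise.
    """

    n_years: int = 21
    start_year: int = 1998
    seasonal_mean_sst: float = 27.0
    seasonal_amp_sst: float = 3.0
    sst_peak_doy: int = 227
    ar1_coef: float = 0.7
    noise_sd: float = 0.5
    warming_trend: float = 0.0          # degC per decade
    injected_events: tuple[InjectedEvent, ...] = ()
    chla_base: float = 0.15             # mg/m3 background
    chla_bloom_amp: float = 0.35        # mg/m3 added at bloom peak
    chla_bloom_peak_doy: int = 32       # about 1 February
    chla_noise_cv: float = 0.3
    coupling_lag_days: int = 3
    missing_fraction: float = 0.1
    outlier_rate: float = 0.001         # per-day probability of a >10 mg/m3 spike
    seed: int = 0

    def __post_init__(self):
        checks = {
            "n_years": self.n_years >= 1,
            "ar1_coef": 0.0 <= self.ar1_coef < 1.0,
            "noise_sd": self.noise_sd >= 0.0,
            "chla_base": self.chla_base > 0.0,
            "chla_bloom_amp": self.chla_bloom_amp >= 0.0,
            "chla_noise_cv": self.chla_noise_cv >= 0.0,
            "coupling_lag_days": self.coupling_lag_days >= 0,
            "missing_fraction": 0.0 <= self.missing_fraction < 1.0,
            "outlier_rate": 0.0 <= self.outlier_rate < 1.0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid ScenarioConfig field {name}={getattr(self, name)!r}")
        object.__setattr__(self, "injected_events", tuple(self.injected_events))

    @property
    def dates(self) -> pd.DatetimeIndex:
        """Daily Gregorian calendar (leap years included) covering the scenario."""
        return pd.date_range(
            f"{self.start_year}-01-01",
            f"{self.start_year + self.n_years - 1}-12-31",
            freq="D",
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a realized scenario."""

    events: tuple[InjectedEvent, ...]
    mld_truth: dict = field(default_factory=dict)


def _seasonal_sst(config: ScenarioConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    doy = dates.dayofyear.to_numpy()
    phase = 2.0 * math.pi * (doy - config.sst_peak_doy) / DAYS_PER_YEAR
    return config.seasonal_mean_sst + config.seasonal_amp_sst * np.cos(phase)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov[t - 1]
    return e


def _event_slice(dates: pd.DatetimeIndex, start: pd.Timestamp, end: pd.Timestamp):
    i0 = dates.searchsorted(start)
    i1 = dates.searchsorted(end, side="right")
    return slice(int(i0), int(i1))


def generate_sst(config: ScenarioConfig) -> tuple[pd.Series, SyntheticTruth]:
    """Daily SST series plus ground truth; identical seeds give identical output."""
    dates = config.dates
    for ev in config.injected_events:
        if ev.start_date < dates[0] or ev.end_date > dates[-1]:
            raise ValueError(
                f"injected event {ev.start_date.date()}+{ev.duration}d lies outside "
                f"the scenario axis {dates[0].date()}..{dates[-1].date()}"
            )
    rng = np.random.default_rng([config.seed, 0])
    n = len(dates)
    values = _seasonal_sst(config, dates)
    years_elapsed = (dates - dates[0]).days.to_numpy() / DAYS_PER_YEAR
    values = values + config.warming_trend / 10.0 * years_elapsed
    values = values + _ar1(rng, n, config.ar1_coef, config.noise_sd)
    for ev in config.injected_events:
        sl = _event_slice(dates, ev.start_date, ev.end_date)
        values[sl] += ev.amplitude if ev.polarity == "warm" else -ev.amplitude
    series = pd.Series(values, index=dates, name="sst")
    return series, SyntheticTruth(events=config.injected_events)


def _bloom_curve(config: ScenarioConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    doy = dates.dayofyear.to_numpy()
    phase = 2.0 * math.pi * (doy - config.chla_bloom_peak_doy) / DAYS_PER_YEAR
    weight = ((1.0 + np.cos(phase)) / 2.0) ** 3  # concentrates the bloom in winter
    return config.chla_base + config.chla_bloom_amp * weight


def generate_chla(config: ScenarioConfig, sst_truth: SyntheticTruth) -> pd.Series:
    """Daily Chl-a series coupled to the scenario's injected SST episodes.

    Values are strictly positive except on injected missing days (NaN) and
    injected outlier days (uniform in (10, 20] mg/m3). The mean level over an
    event's lag-shifted span is the bloom curve times the event's response
    factor, so span means are analytically predictable.
    """
    dates = config.dates
    if config.coupling_lag_days >= len(dates):
        raise ValueError(
            f"coupling_lag_days={config.coupling_lag_days} is not smaller than "
            f"the series length {len(dates)}"
        )
    rng = np.random.default_rng([config.seed, 1])
    n = len(dates)
    mu = _bloom_curve(config, dates)
    lag = pd.Timedelta(days=config.coupling_lag_days)
    for ev in sst_truth.events:
        if ev.chla_response_sign == 0:
            continue
        sl = _event_slice(dates, ev.start_date + lag, ev.end_date + lag)
        mu[sl] *= ev.chla_response_amp
    if config.chla_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.chla_noise_cv**2))
        noise = rng.normal(0.0, sigma, n) - sigma * sigma / 2.0  # mean-corrected
        values = mu * np.exp(noise)
    else:
        values = mu.copy()
    if config.outlier_rate > 0:
        spikes = rng.random(n) < config.outlier_rate
        values[spikes] = rng.uniform(10.0, 20.0, int(spikes.sum()))
    if config.missing_fraction > 0:
        gone = rng.random(n) < config.missing_fraction
        values[gone] = np.nan
    return pd.Series(values, index=dates, name="chla")


def generate_profile(
    surface_temp: float,
    mld_true: float,
    thermocline_gradient: float,
    depths: Sequence[float],
    date="2010-11-15",
    intrusion: tuple[float, float, float] | None = None,
):
    """Idealised temperature profile: isothermal mixed layer over a linear
    thermocline.

    ``thermocline_gradient`` is the cooling rate below the mixed layer in
    degC per metre (>= 0). ``intrusion`` optionally subtracts ``delta`` degC
    inside a (top, bottom) depth band, mimicking a cool subsurface water-mass
    intrusion. Raises if ``mld_true`` is outside the depth span.
    """
    from .mld import TemperatureProfile

    z = np.asarray(depths, dtype=float)
    if z.ndim != 1 or z.size < 2 or not np.all(np.diff(z) > 0):
        raise ValueError("depths must be a strictly increasing sequence of >= 2 levels")
    if not (z[0] <= mld_true <= z[-1]):
        raise ValueError(f"mld_true={mld_true} outside depth span {z[0]}..{z[-1]} m")
    if thermocline_gradient < 0:
        raise ValueError("thermocline_gradient must be >= 0")
    t = np.where(z <= mld_true, surface_temp, surface_temp - thermocline_gradient * (z - mld_true))
    if intrusion is not None:
        top, bottom, delta = intrusion
        t = t - np.where((z >= top) & (z <= bottom), delta, 0.0)
    return TemperatureProfile(date=pd.Timestamp(date), depths=z, temperatures=t)


def generate_sst_field(
    config: ScenarioConfig,
    lats: Sequence[float],
    lons: Sequence[float],
    pixel_noise_sd: float = 0.1,
) -> tuple[xr.DataArray, SyntheticTruth]:
    """Gridded daily SST: the scenario series plus independent pixel noise."""
    series, truth = generate_sst(config)
    rng = np.random.default_rng([config.seed, 2])
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    base = series.to_numpy()[:, None, None]
    noise = rng.normal(0.0, pixel_noise_sd, (len(series), len(lats), len(lons)))
    da = xr.DataArray(
        base + noise,
        dims=("time", "lat", "lon"),
        coords={"time": series.index, "lat": lats, "lon": lons},
        name="sst",
        attrs={"units": "degC", "variable": "sst"},
    )
    return da, truth


def generate_chla_field(
    config: ScenarioConfig,
    sst_truth: SyntheticTruth,
    lats: Sequence[float],
    lons: Sequence[float],
    pixel_noise_cv: float = 0.2,
    dropout_day_fraction: float = 0.05,
) -> xr.DataArray:
    """Gridded daily Chl-a with spatial-coverage dropout days.

    On a random ``dropout_day_fraction`` of days, 75-98% of the pixels are
    missing, which pushes coverage below typical quality-control cut-offs.
    Per-pixel multiplicative noise and rare outlier spikes ride on top of the
    regional series (generated with no missing days; missingness on the grid
    comes from the dropout mechanism).
    """
    cfg = replace(config, missing_fraction=0.0, outlier_rate=0.0)
    series = generate_chla(cfg, sst_truth)
    rng = np.random.default_rng([config.seed, 3])
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    nt, ny, nx = len(series), len(lats), len(lons)
    sigma = math.sqrt(math.log(1.0 + pixel_noise_cv**2)) if pixel_noise_cv > 0 else 0.0
    noise = np.exp(rng.normal(0.0, sigma, (nt, ny, nx)) - sigma * sigma / 2.0)
    values = series.to_numpy()[:, None, None] * noise
    if config.outlier_rate > 0:
        spikes = rng.random((nt, ny, nx)) < config.outlier_rate
        values[spikes] = rng.uniform(10.0, 20.0, int(spikes.sum()))
    if dropout_day_fraction > 0:
        bad_days = rng.random(nt) < dropout_day_fraction
        for ti in np.flatnonzero(bad_days):
            frac = rng.uniform(0.75, 0.98)
            mask = rng.random((ny, nx)) < frac
            values[ti][mask] = np.nan
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": series.index, "lat": lats, "lon": lons},
        name="chla",
        attrs={"units": "mg m-3", "variable": "chla"},
    )
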