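"""Gridded-field operations: region masks, spatial averaging, Chl-a QC.

Gridded inputs are CF-style :class:`xarray.DataArray` objects with
``(time, lat, lon)`` dimensions. Region definitions are plain latitude/
longitude bounding boxes supplied by configuration — the regional split of a
basin is a scientific choice that must come from the user, so the boxes
shipped with the examples are illustrative only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .compound import DEFAULT_BLOOMING_PERIODS, BloomingPeriod

__all__ = [
    "RegionBox",
    "RegionConfig",
    "EXAMPLE_RED_SEA_REGIONS",
    "region_mask",
    "spatial_mean",
    "preprocess_chla",
    "write_netcdf",
]


@dataclass(frozen=True)
class RegionBox:
    """Inclusive latitude/longitude bounds of one region."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self):
        if self.lat_min > self.lat_max or self.lon_min > self.lon_max:
            raise ValueError("region bounds reversed")


@dataclass(frozen=True)
class RegionConfig:
    """Named regions with their blooming windows."""

    boxes: dict[str, RegionBox]
    blooming: dict[str, BloomingPeriod] = field(
        default_factory=lambda: dict(DEFAULT_BLOOMING_PERIODS)
    )

    def __post_init__(self):
        missing = [r for r in self.boxes if r not in self.blooming]
        if missing:
            raise ValueError(f"regions without a blooming window: {missing}")


#: Illustrative four-band split of the Red Sea (latitude bands, not the
#: published region boundaries, which are defined graphically elsewhere).
EXAMPLE_RED_SEA_REGIONS = RegionConfig(
    boxes={
        "NRS": RegionBox(25.5, 30.0, 32.0, 44.0),
        "NCRS": RegionBox(22.0, 25.5, 32.0, 44.0),
        "SCRS": RegionBox(19.0, 22.0, 32.0, 44.0),
        "SRS": RegionBox(12.5, 19.0, 32.0, 44.0),
    }
)


def region_mask(field: xr.DataArray, region: RegionBox | xr.DataArray) -> xr.DataArray:
    """Boolean (lat, lon) mask for a bounding box, or pass a mask through."""
    if isinstance(region, xr.DataArray):
        return region.astype(bool)
    lat_ok = (field["lat"] >= region.lat_min) & (field["lat"] <= region.lat_max)
    lon_ok = (field["lon"] >= region.lon_min) & (field["lon"] <= region.lon_max)
    return (lat_ok & lon_ok).transpose("lat", "lon")


def spatial_mean(
    field: xr.DataArray,
    region: RegionBox | xr.DataArray | None = None,
    latitude_weighted: bool = False,
) -> pd.Series:
    """Daily spatial mean over the valid in-region pixels.

    Days with no valid pixel become missing. The default is an unweighted
    pixel mean; ``latitude_weighted=True`` applies cos(latitude) weights
    (a second-order correction for basins of modest latitude span).
    """
    sub = field
    if region is not None:
        mask = region_mask(field, region)
        if not bool(mask.any()):
            raise ValueError("region mask selects no grid pixels")
        sub = field.where(mask)
    if latitude_weighted:
        w = np.cos(np.deg2rad(sub["lat"]))
        mean = sub.weighted(w).mean(dim=("lat", "lon"), skipna=True)
    else:
        mean = sub.mean(dim=("lat", "lon"), skipna=True)
    out = mean.to_series()
    out.index = pd.DatetimeIndex(out.index)
    out.name = field.name
    return out


def preprocess_chla(
    field: xr.DataArray,
    region: RegionBox | xr.DataArray | None = None,
    min_coverage: float = 0.30,
    max_value: float = 10.0,
    interpolate: bool = True,
) -> pd.Series:
    """Quality-controlled, spatially averaged daily Chl-a series.

    Per day: pixels above ``max_value`` mg/m3 are discarded as spurious;
    coverage is the fraction of region pixels with valid data, and days with
    coverage strictly below ``min_coverage`` are set missing (a day at
    exactly the cut-off is kept); surviving days are spatially averaged.
    Interior missing days of the resulting series are filled by linear
    interpolation in time; leading/trailing gaps stay missing.
    """
    if field.attrs.get("variable", "chla") != "chla":
        raise ValueError(f"expected a chla field, got {field.attrs.get('variable')!r}")
    sub = field
    n_region = int(field.isel(time=0).size)
    if region is not None:
        mask = region_mask(field, region)
        n_region = int(mask.sum())
        if n_region == 0:
            raise ValueError("region mask selects no grid pixels")
        sub = field.where(mask)
    capped = sub.where(sub <= max_value)
    coverage = capped.notnull().sum(dim=("lat", "lon")) / n_region
    daily = capped.mean(dim=("lat", "lon"), skipna=True).where(coverage >= min_coverage)
    series = daily.to_series()
    series.index = pd.DatetimeIndex(series.index)
    series.name = "chla"
    if interpolate:
        series = series.interpolate(method="time", limit_area="inside")
    return series


def write_netcdf(data: xr.Dataset | xr.DataArray, path) -> None:
    """Write a CF-style NetCDF file (classic format)."""
    ds = data.to_dataset() if isinstance(data, xr.DataArray) else data
    ds.to_netcdf(path, engine="scipy")
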