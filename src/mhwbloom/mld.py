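"""Mixed layer depth from discrete temperature profiles.

The MLD criterion is a fixed temperature difference: the mixed layer extends
to the shallowest depth at which temperature has dropped ``delta_t`` (default
0.2 degC) below the reference temperature at ``ref_depth`` (default 10 m).
Depth is positive downward; profiles must already be on depth (not pressure)
levels. The crossing depth is located by linear interpolation between the
bracketing levels, which keeps the estimate independent of grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .climatology import Climatology, day_of_year_365

__all__ = ["TemperatureProfile", "MLDRecord", "compute_mld", "mld_anomaly"]


@dataclass(frozen=True)
class TemperatureProfile:
    """One dated vertical profile; depths strictly increasing downward (m)."""

    date: pd.Timestamp
    depths: np.ndarray
    temperatures: np.ndarray
    salinity: np.ndarray | None = None   # carried for provenance, unused here
    quality: np.ndarray | None = None

    def __post_init__(self):
        z = np.asarray(self.depths, dtype=float)
        t = np.asarray(self.temperatures, dtype=float)
        if z.ndim != 1 or z.size < 2:
            raise ValueError("profile needs at least 2 depth levels")
        if not np.all(np.diff(z) > 0):
            raise ValueError("depths must be strictly increasing downward")
        if t.shape != z.shape:
            raise ValueError("temperatures and depths must have the same length")
        object.__setattr__(self, "date", pd.Timestamp(self.date))
        object.__setattr__(self, "depths", z)
        object.__setattr__(self, "temperatures", t)


@dataclass(frozen=True)
class MLDRecord:
    """MLD estimate for one profile.

    ``method_flag``: "crossed" when the criterion was met inside the profile,
    "bottom_reached" when the deficit never reached ``delta_t`` (MLD set to
    the deepest level), "no_surface_level" when no level near or above the
    reference depth exists (MLD missing).
    """

    date: pd.Timestamp
    mld: float
    method_flag: str


def compute_mld(
    profile: TemperatureProfile,
    ref_depth: float = 10.0,
    delta_t: float = 0.2,
    surface_tolerance: float = 5.0,
) -> MLDRecord:
    """Temperature-difference MLD of one profile.

    The reference temperature is linearly interpolated at ``ref_depth``
    (clamped to the shallowest level if the profile starts slightly below it,
    within ``surface_tolerance`` metres). The MLD is the shallowest depth
    below the reference where ``T_ref - T(z) >= delta_t``, linearly
    interpolated between the bracketing levels.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    z, t = profile.depths, profile.temperatures
    if z[0] > ref_depth + surface_tolerance:
        return MLDRecord(profile.date, float("nan"), "no_surface_level")
    t_ref = float(np.interp(ref_depth, z, t))
    below = z > ref_depth
    deficit = t_ref - t
    crossing = below & (deficit >= delta_t)
    if not crossing.any():
        return MLDRecord(profile.date, float(z[-1]), "bottom_reached")
    j = int(np.argmax(crossing))  # first level meeting the criterion
    if j == 0:
        return MLDRecord(profile.date, float(z[0]), "crossed")
    z0, z1 = z[j - 1], z[j]
    d0, d1 = deficit[j - 1], deficit[j]
    if z0 < ref_depth:  # bracket starts above the reference: anchor there
        z0, d0 = ref_depth, 0.0
    if d1 == d0:
        mld = float(z1)
    else:
        mld = float(z0 + (delta_t - d0) * (z1 - z0) / (d1 - d0))
    return MLDRecord(profile.date, mld, "crossed")


def mld_anomaly(records: Sequence[MLDRecord], baseline) -> pd.Series:
    """Daily MLD anomaly against a calendar-day baseline.

    ``baseline`` is either a :class:`~mhwbloom.climatology.Climatology` built
    from an MLD series (its ``clim_mean`` is used) or a length-365 array /
    Series indexed by calendar-day slot 1..365. Sign convention: deeper than
    the baseline is positive. Raises if the baseline is missing the calendar
    day of any record.
    """
    if isinstance(baseline, Climatology):
        base = np.asarray(baseline.clim_mean, dtype=float)
    elif isinstance(baseline, pd.Series):
        base = np.full(365, np.nan)
        base[np.asarray(baseline.index, dtype=int) - 1] = baseline.to_numpy(dtype=float)
    else:
        base = np.asarray(baseline, dtype=float)
        if base.size != 365:
            raise ValueError("baseline array must have 365 calendar-day values")
    dates = pd.DatetimeIndex([r.date for r in records])
    slots = day_of_year_365(dates) - 1
    vals = np.asarray([r.mld for r in records], dtype=float)
    out = np.empty(len(records))
    for i, (slot, v) in enumerate(zip(slots, vals)):
        b = base[slot]
        if np.isnan(b):
            raise ValueError(f"baseline gap on calendar-day slot {slot + 1}")
        out[i] = v - b
    result = pd.Series(out, index=dates, name="mld_anomaly_m")
    result.attrs["sign_convention"] = "positive = deeper than baseline"
    return result
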