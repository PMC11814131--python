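"""Independent brute-force implementations used as oracles.

Everything here is written as literal, loop-based restatements of the
definitions (explicit pooling, explicit day-by-day scans, closed-form OLS)
and deliberately shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def slot_365(ts: pd.Timestamp) -> int:
    """Calendar-day slot 1..365; 29 Feb maps to the 28 Feb slot."""
    doy = ts.dayofyear
    if ts.is_leap_year and doy > 59:
        doy -= 1
    return doy


def brute_climatology(series: pd.Series, ref_years, percentiles, halfwidth, smooth):
    """Windowed day-of-year statistics via explicit loops."""
    y0, y1 = ref_years
    obs = [
        (slot_365(ts), v)
        for ts, v in series.items()
        if y0 <= ts.year <= y1 and not np.isnan(v)
    ]
    mean = np.empty(365)
    sd = np.empty(365)
    thr = {p: np.empty(365) for p in percentiles}
    for d in range(1, 366):
        wanted = set()
        for off in range(-halfwidth, halfwidth + 1):
            wanted.add((d - 1 + off) % 365 + 1)
        pool = [v for s, v in obs if s in wanted]
        mean[d - 1] = np.mean(pool)
        sd[d - 1] = np.std(pool, ddof=1) if len(pool) > 1 else 0.0
        for p in percentiles:
            thr[p][d - 1] = np.percentile(pool, p)

    def smooth_circ(a):
        half = smooth // 2
        out = np.empty(365)
        for d in range(365):
            out[d] = np.mean([a[(d + off) % 365] for off in range(-half, half + 1)])
        return out

    return smooth_circ(mean), smooth_circ(sd), {p: smooth_circ(v) for p, v in thr.items()}


def brute_detect(values, thr_high, thr_low, min_duration, max_gap, strict=True):
    """Literal threshold/run/merge scan.

    Returns a list of (polarity, i_start, i_end) index spans per the rules:
    exceedance mask (missing days never exceed), maximal runs of length >=
    min_duration, then qualifying runs separated by <= max_gap days merged.
    """
    out = []
    n = len(values)
    for pol, thr in (("high", thr_high), ("low", thr_low)):
        exceed = []
        for i in range(n):
            v = values[i]
            if np.isnan(v):
                exceed.append(False)
            elif pol == "high":
                exceed.append(v > thr[i] if strict else v >= thr[i])
            else:
                exceed.append(v < thr[i] if strict else v <= thr[i])
        runs = []
        i = 0
        while i < n:
            if exceed[i]:
                j = i
                while j + 1 < n and exceed[j + 1]:
                    j += 1
                if j - i + 1 >= min_duration:
                    runs.append([i, j])
                i = j + 1
            else:
                i += 1
        merged = []
        for run in runs:
            if merged and run[0] - merged[-1][1] - 1 <= max_gap:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        out.extend((pol, a, b) for a, b in merged)
    return sorted(out, key=lambda t: (t[1], t[0]))


def brute_match(sst_spans, chla_spans, max_lag):
    """Exhaustive pairwise matching on (start, end) Timestamp spans.

    Concurrency is checked by materialising both day sets and intersecting.
    Returns a set of (i_sst, i_chla, relation) tuples.
    """
    found = set()
    for i, (s0, s1) in enumerate(sst_spans):
        sdays = set(pd.date_range(s0, s1, freq="D"))
        for j, (c0, c1) in enumerate(chla_spans):
            cdays = set(pd.date_range(c0, c1, freq="D"))
            if sdays & cdays:
                found.add((i, j, "concurrent"))
            elif c0 > s1 and (c0 - s1).days <= max_lag:
                found.add((i, j, "lagged"))
    return found


def brute_ols_decadal(years, values):
    """Closed-form OLS slope (per decade) and two-sided t-test p-value."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(years)
    xbar, ybar = years.mean(), values.mean()
    sxx = np.sum((years - xbar) ** 2)
    sxy = np.sum((years - xbar) * (values - ybar))
    beta = sxy / sxx
    alpha_hat = ybar - beta * xbar
    resid = values - alpha_hat - beta * years
    se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
    t = beta / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return beta * 10.0, p


def lag1_autocorr(x):
    """Sample lag-1 autocorrelation by an explicit loop."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    num = 0.0
    den = 0.0
    for i in range(len(x) - 1):
        num += (x[i] - m) * (x[i + 1] - m)
    for i in range(len(x)):
        den += (x[i] - m) ** 2
    return num / den
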