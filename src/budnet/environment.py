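"""Environmental covariates: Utah-model chilling units and day length.

The downstream co-expression analysis correlates module eigengenes against
two anti-correlated winter cues: cumulative chilling units (CHILLING, Utah
model of Richardson 1974) and photoperiod (LOD, hours of daylight). This
module computes both from raw inputs — an hourly (or daily min/max)
temperature record and calendar dates — and assembles the per-sample trait
table.

Conventions
-----------
* The Utah weighting is applied per hourly reading; the chilling series is
  the cumulative sum from a configured start date. Negative daily totals are
  kept by default (``clamp_daily_negative`` clamps them to zero).
* Day length uses the standard sunrise equation with a zenith of 90.833
  degrees (atmospheric refraction plus the solar radius) and the NOAA
  solar-position declination, which tracks published sunrise/sunset tables
  to within a few hundredths of an hour at mid latitudes.
* The default site is Legnaro, Italy (45.35 N, 11.96 E).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_LATITUDE = 45.35
DEFAULT_LONGITUDE = 11.96

# Richardson (1974) Utah temperature bands, upper edge (deg C) -> weight.
# Open-ended top band (> 18.0) contributes -1.0.
_UTAH_UPPER_EDGES = np.array([1.4, 2.4, 9.1, 12.4, 15.9, 18.0])
_UTAH_WEIGHTS = np.array([0.0, 0.5, 1.0, 0.5, 0.0, -0.5])
_UTAH_TOP_WEIGHT = -1.0


def utah_chill_hourly(temp_c):
    """Utah-model chilling contribution of one hour at ``temp_c`` (deg C).

    Piecewise-constant Richardson weighting: 0 for T <= 1.4; 0.5 for
    1.5-2.4; 1.0 for 2.5-9.1; 0.5 for 9.2-12.4; 0 for 12.5-15.9; -0.5 for
    16.0-18.0; -1.0 above 18.0. Band edges are at the published one-decimal
    resolution; temperatures between edges (e.g. 1.45) fall in the band
    whose upper edge they do not exceed.

    Accepts a scalar or array; returns the matching shape.
    """
    arr = np.asarray(temp_c, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite temperature")
    idx = np.searchsorted(_UTAH_UPPER_EDGES, arr, side="left")
    out = np.where(idx < len(_UTAH_WEIGHTS), _UTAH_WEIGHTS[np.minimum(idx, 5)], _UTAH_TOP_WEIGHT)
    if np.isscalar(temp_c) or arr.ndim == 0:
        return float(out)
    return out


def _sine_interpolate_daily(daily: pd.DataFrame, sunrise_hour: float = 6.0,
                            tmax_hour: float = 14.0) -> pd.DataFrame:
    """Reconstruct hourly temperatures from daily min/max.

    Rising half-cosine from the minimum (at ``sunrise_hour``) to the maximum
    (at ``tmax_hour``), falling half-cosine overnight to the next day's
    minimum — standard practice when only daily extremes are recorded.
    """
    days = daily.reset_index(drop=True)
    rows = []
    n = len(days)
    for i in range(n):
        date = pd.Timestamp(days.loc[i, "date"])
        tmin, tmax = float(days.loc[i, "tmin"]), float(days.loc[i, "tmax"])
        next_tmin = float(days.loc[i + 1, "tmin"]) if i + 1 < n else tmin
        for h in range(24):
            if h < sunrise_hour:
                # tail of last night's descent toward today's minimum
                prev_tmax = float(days.loc[i - 1, "tmax"]) if i > 0 else tmax
                frac = (h + 24 - tmax_hour) / (24 - tmax_hour + sunrise_hour)
                temp = prev_tmax + (tmin - prev_tmax) * 0.5 * (1 - math.cos(math.pi * frac))
            elif h <= tmax_hour:
                frac = (h - sunrise_hour) / (tmax_hour - sunrise_hour)
                temp = tmin + (tmax - tmin) * 0.5 * (1 - math.cos(math.pi * frac))
            else:
                frac = (h - tmax_hour) / (24 - tmax_hour + sunrise_hour)
                temp = tmax + (next_tmin - tmax) * 0.5 * (1 - math.cos(math.pi * frac))
            rows.append((date + pd.Timedelta(hours=h), temp))
    return pd.DataFrame(rows, columns=["timestamp", "temp_c"])


def accumulate_chill(
    series: pd.DataFrame,
    start_date: str | _dt.date | None = None,
    clamp_daily_negative: bool = False,
) -> pd.DataFrame:
    """Cumulative Utah chilling units from ``start_date`` onward.

    Parameters
    ----------
    series
        Hourly record with columns ``timestamp`` and ``temp_c``, or a daily
        record with columns ``date``, ``tmin``, ``tmax`` (sine-interpolated
        to hourly first).
    start_date
        First date counted; earlier readings are ignored. Defaults to the
        first date in the series.
    clamp_daily_negative
        If true, negative daily totals are clamped to zero before
        accumulating (the convention is not standardised; unclamped is the
        default).

    Returns
    -------
    DataFrame with one row per calendar day: ``date``, ``cu_daily``,
    ``cu_cumulative``.
    """
    if {"date", "tmin", "tmax"}.issubset(series.columns):
        series = _sine_interpolate_daily(series)
    if not {"timestamp", "temp_c"}.issubset(series.columns):
        raise ValueError("series must have (timestamp,temp_c) or (date,tmin,tmax) columns")
    ts = pd.to_datetime(series["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    gaps = ts.diff().dropna()
    if (gaps > pd.Timedelta(hours=24)).any():
        where = ts[gaps[gaps > pd.Timedelta(hours=24)].index].iloc[0]
        raise ValueError(f"gap longer than 24 h in temperature series at {where}")
    temps = series["temp_c"].to_numpy(dtype=float)
    if start_date is None:
        start = ts.iloc[0].date()
    else:
        start = pd.Timestamp(start_date).date()
        if ts.iloc[-1].date() < start:
            raise ValueError(f"series ends before start date {start}")
    keep = ts.dt.date >= start
    contrib = utah_chill_hourly(temps[keep.to_numpy()])
    daily = pd.DataFrame({"date": ts[keep].dt.date.to_numpy(), "cu": contrib})
    per_day = daily.groupby("date", sort=True)["cu"].sum()
    if clamp_daily_negative:
        per_day = per_day.clip(lower=0.0)
    out = per_day.rename("cu_daily").reset_index()
    out["cu_cumulative"] = out["cu_daily"].cumsum()
    return out


def _solar_declination_deg(date: _dt.date) -> float:
    """Solar declination at local noon, NOAA solar-position algorithm."""
    jd = date.toordinal() + 1721424.5 + 0.5
    jc = (jd - 2451545.0) / 36525.0
    gmls = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    seqc = (
        math.sin(math.radians(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(math.radians(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + math.sin(math.radians(3 * gmas)) * 0.000289
    )
    true_long = gmls + seqc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    return math.degrees(
        math.asin(math.sin(math.radians(obliq)) * math.sin(math.radians(app_long)))
    )


def day_length(
    date: str | _dt.date,
    latitude_deg: float = DEFAULT_LATITUDE,
    longitude_deg: float = DEFAULT_LONGITUDE,
    zenith_deg: float = 90.833,
) -> float:
    """Day length (sunset minus sunrise) in decimal hours.

    Standard sunrise equation with the day's solar declination and a zenith
    of 90.833 deg (refraction + solar radius). Longitude shifts sunrise and
    sunset equally, so it does not enter the duration; it is accepted for
    interface symmetry with site coordinates.

    Raises ``ValueError`` for latitudes at or beyond 66.5 deg and for dates
    where the sun never rises or never sets.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    elif isinstance(date, _dt.datetime):
        date = date.date()
    if abs(latitude_deg) >= 66.5:
        raise ValueError("polar latitudes (|lat| >= 66.5) are not supported")
    decl = math.radians(_solar_declination_deg(date))
    phi = math.radians(latitude_deg)
    cos_h = (math.cos(math.radians(zenith_deg)) - math.sin(phi) * math.sin(decl)) / (
        math.cos(phi) * math.cos(decl)
    )
    if not -1.0 <= cos_h <= 1.0:
        raise ValueError(f"no sunrise/sunset solution for {date} at latitude {latitude_deg}")
    return 2.0 * math.degrees(math.acos(cos_h)) / 15.0


def build_trait_table(
    sample_metadata: pd.DataFrame,
    chilling_series: pd.DataFrame,
    latitude_deg: float = DEFAULT_LATITUDE,
    longitude_deg: float = DEFAULT_LONGITUDE,
) -> pd.DataFrame:
    """Per-sample CHILLING (CU) and LOD (hours) trait table.

    ``sample_metadata`` needs a ``sample_id`` column (or index) and a
    ``date`` column; ``chilling_series`` is the output of
    :func:`accumulate_chill`. Every sampling date must be covered by the
    chilling series.
    """
    meta = sample_metadata.copy()
    if "sample_id" not in meta.columns:
        meta = meta.reset_index().rename(columns={meta.index.name or "index": "sample_id"})
    if meta.empty:
        return pd.DataFrame(columns=["sample_id", "CHILLING", "LOD"])
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample id {dup!r}")
    cu_by_date = {pd.Timestamp(d).date(): c for d, c in
                  zip(chilling_series["date"], chilling_series["cu_cumulative"])}
    rows = []
    for _, rec in meta.iterrows():
        date = pd.Timestamp(rec["date"]).date()
        if date not in cu_by_date:
            raise ValueError(f"sample date {date} not covered by the chilling series")
        rows.append(
            (rec["sample_id"], cu_by_date[date], day_length(date, latitude_deg, longitude_deg))
        )
    return pd.DataFrame(rows, columns=["sample_id", "CHILLING", "LOD"])


def read_temperatures(path: str | Path) -> pd.DataFrame:
    """Read a temperatures CSV: (timestamp,temp_c) or (date,tmin,tmax)."""
    df = pd.read_csv(path)
    if {"timestamp", "temp_c"}.issubset(df.columns) or {"date", "tmin", "tmax"}.issubset(df.columns):
        return df
    raise ValueError("temperatures CSV must have (timestamp,temp_c) or (date,tmin,tmax) columns")
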