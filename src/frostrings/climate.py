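"""Per-year climate indices from daily station records.

Three quantities feed the frost criteria, all defined on fixed austral-spring
windows of the calendar year a ring belongs to (Southern Hemisphere
convention: ring year t <-> spring of calendar year t):

* the annual minimum of daily minimum temperature inside the leaf-unfolding
  window (Oct 1 - Nov 15), standardized across years per station and averaged
  into a regional z-score — cold anomalies during leaf unfolding;
* the frost-risk index FR = mean(tmean, Sep 15 - Oct 15) - min(tmin,
  Oct 1 - Nov 15): a warm early spring (accelerating leaf flush) followed by
  a hard freeze gives a large FR;
* the pinpointed frost day: the day in Oct 1 - Nov 30 maximizing
  d(t) = mean(tmean over the previous 10 days) - tmin(t).

Years in which a station covers less than the configured fraction of window
days (default 90%) are excluded, never filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import StationDaily

MIN_REF_YEARS = 5


@dataclass
class RegionalClimate:
    """Per-region, per-year climate indices.

    ``table`` is year-indexed with columns ``win_min_<station>`` (deg C),
    ``win_min_z`` (regional), ``FR`` (deg C), ``FR_z``, ``excluded`` (bool:
    inadequate daily coverage) and per-station coverage fractions.
    """

    region: str
    table: pd.DataFrame
    stations: list[str]


def _window_days(year: int, window: tuple[str, str]) -> pd.DatetimeIndex:
    lo = pd.Timestamp(f"{year}-{window[0]}")
    hi = pd.Timestamp(f"{year}-{window[1]}")
    return pd.date_range(lo, hi, freq="D")


def _window_values(frame: pd.DataFrame, year: int, window: tuple[str, str],
                   column: str) -> tuple[pd.Series, float]:
    """Values of one column over a month-day window plus coverage fraction."""
    days = _window_days(year, window)
    vals = frame[column].reindex(days).dropna()
    return vals, len(vals) / len(days)


def annual_window_min(
    station: StationDaily,
    years: range | list[int],
    window: tuple[str, str] = ("10-01", "11-15"),
    coverage_threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-year window minimum of daily tmin for one station.

    Returns a year-indexed frame with ``min`` (NaN when coverage fails) and
    ``coverage``.
    """
    rows = {}
    for year in years:
        vals, cov = _window_values(station.frame, year, window, "tmin")
        rows[year] = (vals.min() if cov >= coverage_threshold else np.nan, cov)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["min", "coverage"])
    out.index.name = "year"
    return out


def _standardize_over_ref(series: pd.Series, ref_period: tuple[int, int]) -> pd.Series:
    lo, hi = ref_period
    ref = series.loc[(series.index >= lo) & (series.index <= hi)].dropna()
    if len(ref) < MIN_REF_YEARS:
        raise ValueError(
            f"only {len(ref)} usable reference years in {lo}-{hi} "
            f"(need >= {MIN_REF_YEARS})"
        )
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero variance over reference period {lo}-{hi}")
    return (series - ref.mean()) / sd


def annual_window_min_z(
    stations: list[StationDaily],
    years: range | list[int],
    window: tuple[str, str] = ("10-01", "11-15"),
    ref_period: tuple[int, int] = (1987, 2013),
    coverage_threshold: float = 0.9,
) -> pd.DataFrame:
    """Standardized annual window minima for a two-station region.

    Each station's annual minima are z-scored against its own reference-period
    mean and SD; the regional z is the mean of the station z's. A year failing
    coverage at either station is excluded (NaN everywhere, flag set).
    """
    per_station = {s.station_id: annual_window_min(s, years, window, coverage_threshold)
                   for s in stations}
    out = pd.DataFrame(index=pd.Index(list(years), name="year"))
    zcols = []
    for sid, tab in per_station.items():
        out[f"win_min_{sid}"] = tab["min"]
        out[f"coverage_{sid}"] = tab["coverage"]
        z = _standardize_over_ref(tab["min"], ref_period)
        out[f"win_min_z_{sid}"] = z
        zcols.append(f"win_min_z_{sid}")
    out["excluded"] = out[[f"win_min_{s.station_id}" for s in stations]].isna().any(axis=1)
    out["win_min_z"] = out[zcols].mean(axis=1)
    out.loc[out["excluded"], "win_min_z"] = np.nan
    return out


def frost_risk_index(
    stations: list[StationDaily],
    years: range | list[int],
    warm_window: tuple[str, str] = ("09-15", "10-15"),
    cold_window: tuple[str, str] = ("10-01", "11-15"),
    ref_period: tuple[int, int] = (1987, 2013),
    coverage_threshold: float = 0.9,
) -> pd.DataFrame:
    """Frost-risk index FR per year: warm-window mean temperature minus
    cold-window absolute minimum, averaged over stations, with FR_z
    standardized over the reference period.

    FR is invariant to adding a constant to all temperatures (the two terms
    cancel) and increases when any cold-window minimum drops.
    """
    out = pd.DataFrame(index=pd.Index(list(years), name="year"))
    fr_cols = []
    for s in stations:
        fr = {}
        for year in out.index:
            warm, cov_w = _window_values(s.frame, year, warm_window, "tmean")
            cold, cov_c = _window_values(s.frame, year, cold_window, "tmin")
            ok = cov_w >= coverage_threshold and cov_c >= coverage_threshold
            fr[year] = warm.mean() - cold.min() if ok else np.nan
        col = f"FR_{s.station_id}"
        out[col] = pd.Series(fr)
        fr_cols.append(col)
    out["FR"] = out[fr_cols].mean(axis=1)
    out.loc[out[fr_cols].isna().any(axis=1), "FR"] = np.nan
    out["FR_z"] = _standardize_over_ref(out["FR"], ref_period)
    return out


def regional_daily(stations: list[StationDaily]) -> pd.DataFrame:
    """Composite daily series: per-day mean of tmin and tmean over the days
    present at every station."""
    frames = [s.frame for s in stations]
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    tmin = np.mean([f.loc[common, "tmin"].to_numpy() for f in frames], axis=0)
    tmean = np.mean([f.loc[common, "tmean"].to_numpy() for f in frames], axis=0)
    return pd.DataFrame({"tmin": tmin, "tmean": tmean}, index=common)


def pinpoint_frost_day(
    daily: pd.DataFrame | StationDaily,
    year: int,
    window: tuple[str, str] = ("10-01", "11-30"),
    lookback: int = 10,
) -> tuple[int, float] | None:
    """Day of year on which a frost most plausibly occurred.

    For each day t in the search window with tmin present and a complete
    ``lookback``-day history of tmean, compute d(t) = mean(tmean over
    t-lookback .. t-1) - tmin(t); return (day-of-year, amplitude) of the
    maximum, earliest day on ties. Returns None when no day has d(t) > 0
    (no frost signature). Raises if no day in the window is evaluable.
    """
    frame = daily.frame if isinstance(daily, StationDaily) else daily
    days = _window_days(year, window)
    best: tuple[int, float] | None = None
    evaluable = False
    for day in days:
        if day not in frame.index or pd.isna(frame.at[day, "tmin"]):
            continue
        hist = frame["tmean"].reindex(
            pd.date_range(day - pd.Timedelta(days=lookback), periods=lookback, freq="D")
        )
        if hist.isna().any():
            continue
        evaluable = True
        d = float(hist.mean() - frame.at[day, "tmin"])
        if best is None or d > best[1]:
            best = (int(day.dayofyear), d)
    if not evaluable:
        raise ValueError(f"pinpoint window fully missing in {year}")
    if best is None or best[1] <= 0:
        return None
    return best


def build_regional_climate(
    region: str,
    stations: list[StationDaily],
    years: range | list[int],
    cold_window: tuple[str, str] = ("10-01", "11-15"),
    warm_window: tuple[str, str] = ("09-15", "10-15"),
    ref_period: tuple[int, int] = (1987, 2013),
    coverage_threshold: float = 0.9,
) -> RegionalClimate:
    """Assemble the full per-year index table for one region."""
    wmz = annual_window_min_z(stations, years, cold_window, ref_period,
                              coverage_threshold)
    fr = frost_risk_index(stations, years, warm_window, cold_window,
                          ref_period, coverage_threshold)
    table = wmz.join(fr)
    return RegionalClimate(region=region, table=table,
                           stations=[s.station_id for s in stations])
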