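"""Readers and writers for the standard formats the pipeline touches.

Ring widths travel as Tucson/decadal RWL files (the interchange format of the
ITRDB), daily and monthly station climate as plain CSV, the run configuration
as a flat YAML document, and the reconstructed event table as CSV.

Internally all ring widths are held in millimetres as floats; the file
precision (0.01 or 0.001 mm, signalled by the 999 / -9999 series terminator)
is recorded per series so that a read/write cycle is lossless at the stated
precision.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RingWidthSeries",
    "RingWidthSet",
    "StationDaily",
    "MonthlySeries",
    "DetectionConfig",
    "ParseError",
    "read_rwl",
    "write_rwl",
    "read_daily_climate",
    "write_daily_climate",
    "read_monthly_climate",
    "write_monthly_climate",
    "read_config",
    "write_config",
    "write_event_table",
    "read_event_table",
]

#: Tucson terminators and the measurement precision (mm) they signal.
_SENTINELS = {999: 0.01, -9999: 0.001}

EVENT_TABLE_COLUMNS = [
    "region",
    "site",
    "year",
    "confidence",
    "window_min_station1",
    "window_min_station2",
    "co_drivers",
    "pinpoint_doy",
]


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


@dataclass
class RingWidthSeries:
    """One dated core measurement series, widths in mm."""

    first_year: int
    widths: np.ndarray  # mm, strictly consecutive years
    precision: float = 0.01  # file precision in mm (0.01 or 0.001)

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.size < 1:
            raise ValueError("a series needs at least one width")
        if np.any(self.widths < 0):
            raise ValueError("negative ring width")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.widths.size - 1


@dataclass
class RingWidthSet:
    """Per-site collection of core series under the Southern Hemisphere
    dating convention (a ring belongs to the calendar year in which radial
    growth begins)."""

    site_code: str
    series: dict[str, RingWidthSeries]
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError(f"site {self.site_code}: no series")

    @property
    def year_range(self) -> tuple[int, int]:
        first = min(s.first_year for s in self.series.values())
        last = max(s.last_year for s in self.series.values())
        return first, last

    def to_frame(self) -> pd.DataFrame:
        """Year-indexed width matrix (columns = core ids, NaN outside span)."""
        first, last = self.year_range
        idx = pd.RangeIndex(first, last + 1, name="year")
        data = {}
        for cid, s in self.series.items():
            col = pd.Series(s.widths, index=s.years)
            data[cid] = col.reindex(idx)
        return pd.DataFrame(data, index=idx)


@dataclass
class StationDaily:
    """Daily station record: date-indexed frame with tmin/tmean (deg C).

    Missing days are simply absent from the index; gappy station history is
    excluded downstream, never interpolated, which relies on gaps being
    representable.
    """

    station_id: str
    frame: pd.DataFrame  # DatetimeIndex, columns tmin, tmean

    def __post_init__(self) -> None:
        f = self.frame
        if not f.index.is_monotonic_increasing or f.index.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        bad = f["tmin"] > f["tmean"]
        if bad.any():
            d = f.index[bad][0].date()
            raise ValueError(f"tmin > tmean on {d}")

    @property
    def gaps(self) -> pd.DatetimeIndex:
        """Calendar days absent between the first and last record."""
        full = pd.date_range(self.frame.index[0], self.frame.index[-1], freq="D")
        return full.difference(self.frame.index)


@dataclass
class MonthlySeries:
    """Monthly climate series: values keyed by (year, month)."""

    variable: str  # "temperature" (deg C) or "precipitation" (mm)
    values: pd.Series  # MultiIndex (year, month)

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            raise ValueError("duplicate (year, month)")
        months = idx.get_level_values(1)
        if ((months < 1) | (months > 12)).any():
            raise ValueError("month outside 1..12")


# --------------------------------------------------------------------------
# Tucson / decadal RWL


def read_rwl(path: str | Path) -> RingWidthSet:
    """Parse a Tucson/decadal ring-width file into a :class:`RingWidthSet`.

    Each data row carries a series id, the calendar year of its first value
    and up to ten integer widths; a series ends with the 999 (0.01 mm) or
    -9999 (0.001 mm) terminator, from which the precision is auto-detected.
    An optional 3-line ITRDB header block is skipped, not interpreted.
    """
    path = Path(path)
    raw: dict[str, list[int]] = {}
    first_year: dict[str, int] = {}
    expect_year: dict[str, int] = {}
    data_started = False
    row_re = re.compile(r"^(\S+)\s+(-?\d+)((?:\s+-?\d+)+)\s*$")

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            m = row_re.match(line.rstrip())
            if m is None:
                # tolerate an ITRDB header block before any data row
                if not data_started and lineno <= 3:
                    continue
                raise ParseError(f"{path.name}:{lineno}: malformed row")
            data_started = True
            sid, year = m.group(1), int(m.group(2))
            values = [int(v) for v in m.group(3).split()]
            if sid not in raw:
                raw[sid] = []
                first_year[sid] = year
                expect_year[sid] = year
            elif year != expect_year[sid]:
                if year < expect_year[sid]:
                    raise ParseError(
                        f"{path.name}:{lineno}: duplicate year {year} "
                        f"in series {sid}"
                    )
                raise ParseError(
                    f"{path.name}:{lineno}: series {sid} jumps from "
                    f"{expect_year[sid]} to {year} (non-consecutive decades)"
                )
            raw[sid].extend(values)
            expect_year[sid] += len(values)

    series = {}
    for sid, values in raw.items():
        if not values or values[-1] not in _SENTINELS:
            raise ParseError(f"{path.name}: series {sid} lacks a terminator")
        precision = _SENTINELS[values[-1]]
        body = values[:-1]
        if not body:
            raise ParseError(f"{path.name}: series {sid} has no data")
        if any(v < 0 for v in body):
            raise ParseError(f"{path.name}: series {sid}: negative width")
        series[sid] = RingWidthSeries(
            first_year=first_year[sid],
            widths=np.asarray(body, dtype=float) * precision,
            precision=precision,
        )
    if not series:
        raise ParseError(f"{path.name}: no series found")
    return RingWidthSet(site_code=path.stem, series=series)


def write_rwl(rw: RingWidthSet, path: str | Path) -> None:
    """Write a :class:`RingWidthSet` as decadal Tucson rows.

    The first row of a series runs from its first year to the end of that
    decade; subsequent rows hold ten values each; the terminator matching the
    recorded precision closes the series.
    """
    path = Path(path)
    lines = []
    for sid, s in rw.series.items():
        sentinel = 999 if s.precision == 0.01 else -9999
        ints = np.rint(s.widths / s.precision).astype(int)
        year = s.first_year
        pos = 0
        while pos < ints.size:
            row_len = 10 - (year % 10)
            chunk = ints[pos : pos + row_len]
            vals = list(chunk)
            pos += len(chunk)
            if pos >= ints.size:
                vals.append(sentinel)
            lines.append(
                f"{sid:<8s}{year:>6d}" + "".join(f"{v:>6d}" for v in vals)
            )
            year += len(chunk)
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Climate CSV


def read_daily_climate(path: str | Path, station_id: str | None = None) -> StationDaily:
    """Read a daily station CSV with header ``date,tmin,tmean`` (ISO dates)."""
    path = Path(path)
    df = pd.read_csv(path)
    expected = {"date", "tmin", "tmean"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path.name}: header must contain {sorted(expected)}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path.name}: unparseable date ({exc})") from exc
    frame = pd.DataFrame(
        {"tmin": df["tmin"].astype(float).values,
         "tmean": df["tmean"].astype(float).values},
        index=pd.DatetimeIndex(dates),
    ).sort_index()
    return StationDaily(station_id=station_id or path.stem, frame=frame)


def write_daily_climate(station: StationDaily, path: str | Path) -> None:
    out = station.frame.reset_index(names="date")
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=["date", "tmin", "tmean"])


def read_monthly_climate(path: str | Path, variable: str) -> MonthlySeries:
    """Read a monthly CSV with header ``year,month,value``."""
    df = pd.read_csv(Path(path))
    idx = pd.MultiIndex.from_arrays(
        [df["year"].astype(int), df["month"].astype(int)], names=["year", "month"]
    )
    return MonthlySeries(variable=variable, values=pd.Series(df["value"].astype(float).values, index=idx))


def write_monthly_climate(series: MonthlySeries, path: str | Path) -> None:
    out = series.values.rename("value").reset_index()
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Configuration


@dataclass
class DetectionConfig:
    """All knobs of the detection procedure, in one validated document.

    Defaults are the published thresholds: site reductions and cold anomalies
    at 1.5 SD, control-species reduction at 1.5 SD, monthly-climate deviation
    at 1 SD, Cropper value 0.5 with a strict >50% series proportion, frost
    risk flagged above +1.5 SD; reference periods 1950-1991 (local
    reductions), 1950-2003 (control species and monthly deviations) and
    1987-2013 (daily standardization).
    """

    regions: dict[str, list[str]] = field(default_factory=dict)  # region -> site codes
    control_regions: dict[str, list[str]] = field(default_factory=dict)
    stations: dict[str, list[str]] = field(default_factory=dict)  # region -> 2 station ids
    c1_ref_period: tuple[int, int] = (1950, 1991)
    c34_ref_period: tuple[int, int] = (1950, 2003)
    daily_ref_period: tuple[int, int] = (1987, 2013)
    local_reduction_sd: float = 1.5
    cold_z: float = -1.5
    control_sd: float = 1.5
    climate_deviation_sd: float = 1.0
    cropper_threshold: float = 0.5
    pointer_proportion: float = 0.5
    pointer_min_series: int = 5
    fr_z: float = 1.5
    cold_window: tuple[str, str] = ("10-01", "11-15")  # month-day, austral spring
    warm_window: tuple[str, str] = ("09-15", "10-15")
    pinpoint_window: tuple[str, str] = ("10-01", "11-30")
    coverage_threshold: float = 0.9
    correlation_alpha: float = 0.01
    two_sided_deviations: bool = False
    require_additional_for_low: bool = True
    c3_failure_downgrades: bool = True
    outbreak_years: dict[str, list[int]] = field(default_factory=dict)  # region -> years
    documented_frost_years: dict[str, list[int]] = field(default_factory=dict)
    fallback_key_variables: dict[str, list[str]] = field(default_factory=dict)
    # region -> e.g. ["temperature:11", "temperature:12", "precipitation:11"]

    def __post_init__(self) -> None:
        for name in ("local_reduction_sd", "control_sd", "climate_deviation_sd",
                     "cropper_threshold", "fr_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("c1_ref_period", "c34_ref_period", "daily_ref_period"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name}: empty year range")
        self.c1_ref_period = tuple(self.c1_ref_period)
        self.c34_ref_period = tuple(self.c34_ref_period)
        self.daily_ref_period = tuple(self.daily_ref_period)
        self.cold_window = tuple(self.cold_window)
        self.warm_window = tuple(self.warm_window)
        self.pinpoint_window = tuple(self.pinpoint_window)

    def region_of(self, site_code: str) -> str:
        for region, sites in self.regions.items():
            if site_code in sites:
                return region
        for region, sites in self.control_regions.items():
            if site_code in sites:
                return region
        raise KeyError(f"site {site_code} not assigned to any region")


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(DetectionConfig)}


def read_config(path: str | Path) -> DetectionConfig:
    """Load a YAML config; unknown keys are rejected so threshold typos fail
    loudly instead of silently reverting to defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise ParseError(f"{Path(path).name}: config must be a mapping")
    unknown = set(doc) - _CONFIG_FIELDS
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    return DetectionConfig(**doc)


def write_config(config: DetectionConfig, path: str | Path) -> None:
    doc = dataclasses.asdict(config)
    for key, val in doc.items():
        if isinstance(val, tuple):
            doc[key] = list(val)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# --------------------------------------------------------------------------
# Event table


def write_event_table(events, path: str | Path) -> None:
    """Write a reconstructed-event table (or its DataFrame) as CSV."""
    frame = events.to_frame() if hasattr(events, "to_frame") else events
    frame = frame.reindex(columns=EVENT_TABLE_COLUMNS)
    frame.to_csv(path, index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), dtype={"co_drivers": "string"})
    df["co_drivers"] = df["co_drivers"].fillna("")
    if "pinpoint_doy" in df.columns:
        df["pinpoint_doy"] = df["pinpoint_doy"].astype("Int64")
    return df
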