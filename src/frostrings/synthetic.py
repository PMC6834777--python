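"""Synthetic tree-ring networks and station climate with injected events.

The generator emulates the statistical structure the detection procedure
assumes: multi-core per-tree width series composed multiplicatively of a
negative-exponential age curve, a shared regional high-frequency signal
(partly driven by spring/early-summer temperature), site- and tree-level
noise with lag-1 autocorrelation, and core measurement noise; daily station
temperatures with a seasonal cycle, AR(1) weather anomalies shared within a
region, and a diurnal offset between mean and minimum; monthly temperature
aggregated from the daily series and seasonal gamma-distributed
precipitation.

Injected events come in two kinds. A *frost* multiplies the widths of the
affected deciduous sites in the event year by (1 - reduction) and writes a
warm spell followed by a 1-3 day cold snap into the daily series, the snap
minimum placed a fixed number of SD below the climatological window
minimum. A *drought* multiplies all sites of the region — deciduous targets
and evergreen controls alike — leaving the daily series untouched. Frost
years are generated as otherwise climatically ordinary: the region's weather
anomaly is shrunk toward climatology in those years so that the injected
episode is the only anomaly (switchable via ``event_damp``).

All randomness flows from ``params.seed``; identical parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import (
    DetectionConfig,
    MonthlySeries,
    RingWidthSeries,
    RingWidthSet,
    StationDaily,
)

__all__ = [
    "InjectedEvent",
    "SimulationParams",
    "DailySimResult",
    "NetworkData",
    "simulate_daily_temperature",
    "simulate_ring_widths",
    "simulate_network",
    "demo_params",
]


@dataclass
class InjectedEvent:
    type: str  # "frost" | "drought"
    year: int
    region: str
    sites: list[str] = field(default_factory=list)  # frost: affected targets
    reduction: float = 0.5  # growth reduction fraction in (0, 1)
    cold_snap_sd: float = 2.5  # snap depth below window-min climatology
    cold_snap_days: int = 2
    warm_spell_days: int = 8
    warm_spell_delta: float = 5.0  # degC added during the warm spell
    with_warm_spell: bool = True
    documented: bool = False  # appears in the documented frost-record list

    def __post_init__(self) -> None:
        if self.type not in ("frost", "drought"):
            raise ValueError(f"unknown event type {self.type!r}")
        if not 0.0 < self.reduction < 1.0:
            raise ValueError("reduction fraction must lie in (0, 1)")
        if not 1 <= self.cold_snap_days <= 3:
            raise ValueError("cold snap lasts 1-3 days")


@dataclass
class SimulationParams:
    """Study conditions of the simulated network.

    Defaults mirror a scaled-down two-network deciduous/evergreen design:
    three regions of ten deciduous sites (plus three evergreen-control sites)
    with fifteen trees x two cores per site over 80 years (1939-2018, so the
    default reference periods of the detector all fit inside the simulated
    span).
    """

    n_regions: int = 3
    sites_per_region: int = 10
    control_sites_per_region: int = 3
    trees_per_site: int = 15
    cores_per_tree: int = 2
    n_years: int = 80
    start_year: int = 1939
    # negative-exponential age curve w(t) = a*exp(-b*t) + c, per tree (mm)
    age_a_range: tuple[float, float] = (0.5, 2.0)
    age_b_range: tuple[float, float] = (0.02, 0.08)
    age_c_range: tuple[float, float] = (0.3, 0.8)
    max_start_offset: int = 15  # staggered tree establishment (years)
    phi: float = 0.3  # lag-1 autocorrelation of tree-level noise
    regional_sd: float = 0.12  # log-scale SD of the shared regional signal
    site_sd: float = 0.08
    tree_sd: float = 0.15
    core_sd: float = 0.05
    climate_coupling: float = 0.5  # share of regional signal driven by Nov-Dec T
    # daily climate
    seasonal_mean: float = 8.0  # degC, annual mean
    seasonal_amp: float = 7.0  # degC, half-range of the seasonal cycle
    warmest_doy: int = 15  # mid-January (austral summer)
    diurnal_offset: float = 6.0  # tmean - tmin, degC
    weather_ar: float = 0.7  # AR(1) coefficient of daily weather anomalies
    weather_sd: float = 2.0  # stationary SD of the shared regional anomaly
    station_sd: float = 1.0  # station-specific anomaly SD
    tmin_noise_sd: float = 1.0
    event_damp: float = 0.25  # anomaly shrink factor in frost-event years
    # monthly precipitation (winter-wet seasonal gamma)
    precip_base: float = 60.0  # mm
    precip_amp: float = 40.0
    precip_peak_month: int = 7
    precip_shape: float = 4.0
    events: list[InjectedEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 60:
            raise ValueError("n_years must be >= 60 (reference periods must fit)")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")
        for ev in self.events:
            y0, y1 = self.start_year, self.start_year + self.n_years - 1
            if not y0 <= ev.year <= y1:
                raise ValueError(f"event year {ev.year} outside {y0}-{y1}")

    @property
    def regions(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def target_sites(self, region: str) -> list[str]:
        return [f"{region}s{i + 1:02d}" for i in range(self.sites_per_region)]

    def control_sites(self, region: str) -> list[str]:
        return [f"{region}c{i + 1:02d}" for i in range(self.control_sites_per_region)]


@dataclass
class DailySimResult:
    stations: list[StationDaily]
    snap_days: dict[int, pd.Timestamp]  # frost-event year -> first snap day


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def _ar1(rng: np.random.Generator, n: int, coef: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - coef**2) if coef > 0 else sd
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for i in range(1, n):
        x[i] = coef * x[i - 1] + eps[i]
    return x


def _window_mask(dates: pd.DatetimeIndex, year: int, lo: str, hi: str) -> np.ndarray:
    return (dates >= pd.Timestamp(f"{year}-{lo}")) & (dates <= pd.Timestamp(f"{year}-{hi}"))


def simulate_daily_temperature(params: SimulationParams, region: str) -> DailySimResult:
    """Two correlated daily stations for one region, with frost episodes.

    Each station's tmean is seasonal cycle + shared regional AR(1) anomaly +
    station-specific AR(1) anomaly; tmin sits a diurnal offset below tmean
    plus bounded noise, so tmin <= tmean always. In frost-event years the
    anomalies are shrunk by ``event_damp`` and a warm spell (inside
    Sep 15 - Oct 15) followed by a cold snap (inside Oct 1 - Nov 15) is
    written in; the snap minimum is placed ``cold_snap_sd`` SD below the
    station's climatological window-minimum mean.
    """
    ridx = params.regions.index(region)
    rng = _rng(params, 1000 + ridx)
    y0, y1 = params.start_year, params.start_year + params.n_years - 1
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = params.seasonal_mean + params.seasonal_amp * np.cos(
        2.0 * np.pi * (doy - params.warmest_doy) / 365.25
    )
    shared = _ar1(rng, n, params.weather_ar, params.weather_sd)

    frost_events = [e for e in params.events
                    if e.region == region and e.type == "frost"]
    damp = np.ones(n)
    for ev in frost_events:
        # a clean frost year is climatically ordinary over the whole
        # attribution window, which runs through March of the next year
        damp[dates.year == ev.year] = params.event_damp
        damp[(dates.year == ev.year + 1) & (dates.month <= 3)] = params.event_damp

    frames = []
    base_tmins = []
    for s in range(2):
        own = _ar1(rng, n, params.weather_ar, params.station_sd)
        tmean = seasonal + (shared + own) * damp
        dn = np.minimum(rng.normal(0.0, params.tmin_noise_sd, size=n),
                        params.diurnal_offset)
        tmin = tmean - params.diurnal_offset + dn
        frames.append(pd.DataFrame({"tmin": tmin, "tmean": tmean}, index=dates))
        base_tmins.append(tmin.copy())

    # climatology of the cold-window minima, from the pre-injection series
    clim = []
    for tmin in base_tmins:
        mins = []
        for year in params.years:
            m = _window_mask(dates, year, "10-01", "11-15")
            mins.append(tmin[m].min())
        mins = np.asarray(mins)
        clim.append((mins.mean(), mins.std(ddof=1)))

    snap_days: dict[int, pd.Timestamp] = {}
    for ev in frost_events:
        warm_lo = pd.Timestamp(f"{ev.year}-09-15")
        warm_hi = pd.Timestamp(f"{ev.year}-10-15")
        spell_end = warm_hi
        if ev.with_warm_spell and ev.warm_spell_days > 0:
            latest_start = warm_hi - pd.Timedelta(days=ev.warm_spell_days - 1)
            span = (latest_start - warm_lo).days
            start = warm_lo + pd.Timedelta(days=int(rng.integers(0, span + 1)))
            spell_end = start + pd.Timedelta(days=ev.warm_spell_days - 1)
            spell = (dates >= start) & (dates <= spell_end)
            for f in frames:
                f.loc[spell, ["tmin", "tmean"]] += ev.warm_spell_delta
        snap_lo = max(pd.Timestamp(f"{ev.year}-10-01"),
                      spell_end + pd.Timedelta(days=2))
        snap_hi = pd.Timestamp(f"{ev.year}-11-15") - pd.Timedelta(days=ev.cold_snap_days - 1)
        offset = int(rng.integers(0, max((snap_hi - snap_lo).days, 0) + 1))
        snap_start = snap_lo + pd.Timedelta(days=offset)
        snap = (dates >= snap_start) & \
               (dates < snap_start + pd.Timedelta(days=ev.cold_snap_days))
        for f, (mu, sd) in zip(frames, clim):
            target = mu - ev.cold_snap_sd * sd
            f.loc[snap, "tmin"] = np.minimum(f.loc[snap, "tmin"], target)
            f.loc[snap, "tmean"] = np.minimum(f.loc[snap, "tmean"],
                                              f.loc[snap, "tmin"] + 3.0)
        snap_days[ev.year] = snap_start

    stations = [StationDaily(station_id=f"{region}_st{s + 1}", frame=f)
                for s, f in enumerate(frames)]
    return DailySimResult(stations=stations, snap_days=snap_days)


def _novdec_temperature_z(stations: list[StationDaily],
                          years: np.ndarray) -> np.ndarray:
    """Standardized Nov-Dec composite mean temperature per year (the climate
    driver of the regional growth signal)."""
    comp = np.mean([s.frame["tmean"].to_numpy() for s in stations], axis=0)
    dates = stations[0].frame.index
    vals = np.array([
        comp[(dates.year == y) & (dates.month >= 11)].mean() for y in years
    ])
    sd = vals.std(ddof=1)
    return (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)


def simulate_ring_widths(
    params: SimulationParams,
    region: str,
    daily: DailySimResult | None = None,
) -> tuple[dict[str, RingWidthSet], dict[str, RingWidthSet]]:
    """Deciduous target and evergreen control ring-width sets for one region.

    width(core, t) = ageCurve(t) * exp(regional(t) + site(t) + tree(t) +
    core(t)) * eventFactor(t). The regional signal is a mixture of the
    standardized Nov-Dec temperature of the region's simulated stations
    (weight ``climate_coupling``) and white noise. Frost events multiply the
    affected target sites by (1 - reduction); droughts multiply every site
    of the region in both networks.
    """
    ridx = params.regions.index(region)
    rng = _rng(params, 2000 + ridx)
    years = params.years
    ny = params.n_years

    if daily is None:
        daily = simulate_daily_temperature(params, region)
    zclim = _novdec_temperature_z(daily.stations, years)
    cc = params.climate_coupling
    regional = params.regional_sd * (
        cc * zclim + np.sqrt(max(1.0 - cc**2, 0.0)) * rng.normal(size=ny)
    )

    frost_factor: dict[str, np.ndarray] = {}
    drought_factor = np.ones(ny)
    for ev in params.events:
        if ev.region != region:
            continue
        yi = int(ev.year - params.start_year)
        if ev.type == "drought":
            drought_factor[yi] *= 1.0 - ev.reduction
        else:
            for code in ev.sites:
                frost_factor.setdefault(code, np.ones(ny))[yi] *= 1.0 - ev.reduction

    def make_site(code: str, is_control: bool) -> RingWidthSet:
        site_sig = rng.normal(0.0, params.site_sd, size=ny)
        factor = drought_factor.copy()
        if not is_control and code in frost_factor:
            factor = factor * frost_factor[code]
        series: dict[str, RingWidthSeries] = {}
        for tr in range(params.trees_per_site):
            a = rng.uniform(*params.age_a_range)
            b = rng.uniform(*params.age_b_range)
            c = rng.uniform(*params.age_c_range)
            offset = int(rng.integers(0, params.max_start_offset + 1))
            span = ny - offset
            t = np.arange(span, dtype=float)
            age = a * np.exp(-b * t) + c
            tree_sig = _ar1(rng, span, params.phi, params.tree_sd)
            logs = regional[offset:] + site_sig[offset:] + tree_sig
            for co in range(params.cores_per_tree):
                core_sig = rng.normal(0.0, params.core_sd, size=span)
                widths = age * np.exp(logs + core_sig) * factor[offset:]
                series[f"{code}t{tr + 1:02d}{chr(97 + co)}"] = RingWidthSeries(
                    first_year=int(years[offset]), widths=widths, precision=0.01
                )
        tag = "evergreen-control" if is_control else "deciduous-target"
        return RingWidthSet(site_code=code, series=series, species_tag=tag)

    targets = {c: make_site(c, False) for c in params.target_sites(region)}
    controls = {c: make_site(c, True) for c in params.control_sites(region)}
    return targets, controls


def _monthly_from_daily(stations: list[StationDaily]) -> MonthlySeries:
    comp = np.mean([s.frame["tmean"].to_numpy() for s in stations], axis=0)
    dates = stations[0].frame.index
    df = pd.DataFrame({"v": comp, "year": dates.year, "month": dates.month})
    agg = df.groupby(["year", "month"])["v"].mean()
    return MonthlySeries(variable="temperature", values=agg)


def _simulate_precipitation(params: SimulationParams, region: str) -> MonthlySeries:
    ridx = params.regions.index(region)
    rng = _rng(params, 3000 + ridx)
    frost_years = {e.year for e in params.events
                   if e.region == region and e.type == "frost"}
    rows = {}
    for year in params.years:
        for month in range(1, 13):
            mean = params.precip_base + params.precip_amp * np.cos(
                2.0 * np.pi * (month - params.precip_peak_month) / 12.0
            )
            # frost years are climatically ordinary over the full
            # Jan(t)..Mar(t+1) attribution window
            clean = year in frost_years or (year - 1 in frost_years and month <= 3)
            if clean:
                rows[(year, month)] = mean
            else:
                rows[(year, month)] = rng.gamma(
                    params.precip_shape, mean / params.precip_shape
                )
    values = pd.Series(rows)
    values.index.names = ["year", "month"]
    return MonthlySeries(variable="precipitation", values=values)


@dataclass
class NetworkData:
    params: SimulationParams
    targets: dict[str, RingWidthSet]
    controls: dict[str, RingWidthSet]
    stations: dict[str, list[StationDaily]]
    monthly: dict[str, dict[str, MonthlySeries]]
    snap_days: dict[str, dict[int, pd.Timestamp]]
    truth: pd.DataFrame  # one row per injected event

    def make_config(self, **overrides) -> DetectionConfig:
        params = self.params
        cfg = DetectionConfig(
            regions={r: params.target_sites(r) for r in params.regions},
            control_regions={r: params.control_sites(r) for r in params.regions},
            stations={r: [s.station_id for s in self.stations[r]]
                      for r in params.regions},
            fallback_key_variables={
                r: ["temperature:nov", "temperature:dec"] for r in params.regions
            },
            documented_frost_years={
                r: sorted(e.year for e in params.events
                          if e.region == r and e.type == "frost" and e.documented)
                for r in params.regions
            },
        )
        for key, val in overrides.items():
            setattr(cfg, key, val)
        return cfg


def simulate_network(params: SimulationParams) -> NetworkData:
    """Generate the full multi-region network plus its ground-truth table."""
    targets: dict[str, RingWidthSet] = {}
    controls: dict[str, RingWidthSet] = {}
    stations: dict[str, list[StationDaily]] = {}
    monthly: dict[str, dict[str, MonthlySeries]] = {}
    snap_days: dict[str, dict[int, pd.Timestamp]] = {}
    for region in params.regions:
        daily = simulate_daily_temperature(params, region)
        stations[region] = daily.stations
        snap_days[region] = daily.snap_days
        tg, ct = simulate_ring_widths(params, region, daily=daily)
        targets.update(tg)
        controls.update(ct)
        monthly[region] = {
            "temperature": _monthly_from_daily(daily.stations),
            "precipitation": _simulate_precipitation(params, region),
        }
    rows = []
    for ev in params.events:
        sites = ev.sites if ev.type == "frost" else params.target_sites(ev.region)
        snap = snap_days[ev.region].get(ev.year)
        rows.append({
            "type": ev.type, "year": ev.year, "region": ev.region,
            "sites": ";".join(sites), "reduction": ev.reduction,
            "snap_doy": int(snap.dayofyear) if snap is not None else pd.NA,
            "documented": ev.documented,
        })
    truth = pd.DataFrame(
        rows, columns=["type", "year", "region", "sites", "reduction",
                       "snap_doy", "documented"])
    truth["snap_doy"] = truth["snap_doy"].astype("Int64")
    return NetworkData(params=params, targets=targets, controls=controls,
                       stations=stations, monthly=monthly,
                       snap_days=snap_days, truth=truth)


def demo_params(seed: int = 0, n_regions: int = 2, sites_per_region: int = 6,
                trees_per_site: int = 15, with_events: bool = True,
                **overrides) -> SimulationParams:
    """Canonical two-region demonstration design: six injected frosts
    (reductions 0.4-0.6, cold snaps of 2.5 SD, 8-day warm spells, two sites
    each) and four regional droughts over 80 years."""
    events: list[InjectedEvent] = []
    if with_events:
        frost_years = {"R1": [1957, 1980, 1992], "R2": [1965, 1974, 2002]}
        drought_years = {"R1": [1962, 1998], "R2": [1952, 1988]}
        reductions = [0.4, 0.5, 0.6]
        for r_i, region in enumerate(f"R{i + 1}" for i in range(n_regions)):
            for k, year in enumerate(frost_years.get(region, [])):
                first = (k * 2) % sites_per_region
                sites = [f"{region}s{first + 1:02d}",
                         f"{region}s{(first + 1) % sites_per_region + 1:02d}"]
                events.append(InjectedEvent(
                    type="frost", year=year, region=region, sites=sites,
                    reduction=reductions[k % 3], cold_snap_sd=2.5,
                    warm_spell_days=8, documented=(k == 1),
                ))
            for year in drought_years.get(region, []):
                events.append(InjectedEvent(type="drought", year=year,
                                            region=region, reduction=0.45))
    return SimulationParams(
        n_regions=n_regions, sites_per_region=sites_per_region,
        trees_per_site=trees_per_site, events=events, seed=seed, **overrides)
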