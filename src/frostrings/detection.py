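"""Multi-criteria detection of spring-frost growth reductions.

Five eliminatory criteria and two additional (confidence-raising) criteria
are evaluated per site-year:

* C1 — the site chronology lies more than 1.5 SD below the leave-one-out
  regional chronology (local growth reduction);
* C2 — the regional standardized window minimum temperature during leaf
  unfolding is below -1.5 (a hard spring freeze);
* C3 — the evergreen control-species regional chronology shows *no*
  reduction below 1.5 SD (separating frosts, which spare evergreen foliage,
  from droughts and other shared disturbances);
* C4 — no key monthly climate variable deviates adversely beyond 1 SD
  (the reduction is not explained by ordinary climate);
* C5 — the year carries no documented or reconstructed insect outbreak;
* A1 — the year is a negative pointer year (a strict majority of series
  with Cropper values below -0.5);
* A2 — the frost-risk index is high (z > 1.5: warm early spring followed by
  a hard freeze).

Site-years passing C1, C2 and C5 enter the event table; the confidence level
follows a four-step scale: *high uncertainty* (only the gates), *medium*
(an additional criterion holds but C3 or C4 fails, the failure recorded as a
co-driver), *low* (C3, C4 and an additional criterion all hold) and
*validated* (low, plus a documented frost record for that region and year).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import climate as _climate
from . import growth_climate as _gc
from .chronology import (
    RegionalChronology,
    SiteChronology,
    build_regional_chronology,
    build_site_chronology,
)
from .data_io import (
    EVENT_TABLE_COLUMNS,
    DetectionConfig,
    MonthlySeries,
    RingWidthSet,
    StationDaily,
)
from .util import zscore_ref

logger = logging.getLogger(__name__)

CONFIDENCE_ORDER = ["validated", "low", "medium", "high"]  # best to worst


@dataclass
class FrostEventTable:
    """Reconstructed events with confidence levels and supporting values."""

    frame: pd.DataFrame  # columns EVENT_TABLE_COLUMNS

    def to_frame(self) -> pd.DataFrame:
        return self.frame.reindex(columns=EVENT_TABLE_COLUMNS)

    def __len__(self) -> int:
        return len(self.frame)


# --------------------------------------------------------------------------
# Criterion 1 — local growth reductions


def local_growth_reductions(
    site: SiteChronology,
    regional: RegionalChronology,
    threshold: float = 1.5,
    ref_period: tuple[int, int] = (1950, 1991),
) -> pd.DataFrame:
    """Flag years where the site chronology sits more than ``threshold`` SD
    below the leave-one-out regional chronology.

    The difference series d(t) = site(t) - regional(t) is standardized over
    the reference period; years with z strictly below -threshold are flagged.
    """
    d = site.index - regional.index
    z = zscore_ref(d, ref_period)
    out = pd.DataFrame({"d": d, "z": z})
    out["flag"] = z < -threshold
    out.loc[z.isna(), "flag"] = False
    return out


# --------------------------------------------------------------------------
# Additional criterion 1 — pointer years from Cropper values


def cropper_values(indices: pd.DataFrame, window: int = 5) -> pd.DataFrame:
    """Normalized growth deviations within a moving window, per series.

    For each series and year t, c_t = (x_t - mean(window centered on t)) /
    SD(window), with the window truncated at the series edges and the sample
    SD (ddof=1); a zero-SD window yields c_t = 0.
    """
    half = window // 2
    out = pd.DataFrame(np.nan, index=indices.index, columns=indices.columns)
    years = indices.index.to_numpy()
    for col in indices.columns:
        x = indices[col]
        valid = x.dropna()
        for y in valid.index:
            lo, hi = y - half, y + half
            win = valid.loc[(valid.index >= lo) & (valid.index <= hi)]
            sd = win.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                out.at[y, col] = 0.0
            else:
                out.at[y, col] = (valid.at[y] - win.mean()) / sd
    return out


def pointer_years(
    cropper: pd.DataFrame,
    value_threshold: float = 0.5,
    proportion: float = 0.5,
    min_series: int = 5,
) -> pd.DataFrame:
    """Negative pointer years: a strict majority of the series present shows
    a Cropper value strictly below -value_threshold.

    Years with fewer than ``min_series`` series present are marked not
    evaluable (flag False).
    """
    present = cropper.notna().sum(axis=1)
    below = (cropper < -value_threshold).sum(axis=1)
    frac = below / present.replace(0, np.nan)
    evaluable = present >= min_series
    return pd.DataFrame({
        "n_series": present,
        "n_below": below,
        "fraction": frac,
        "evaluable": evaluable,
        "flag": evaluable & (frac > proportion),
    })


# --------------------------------------------------------------------------
# Integration


def _is_true(value) -> bool:
    """True only for an actual affirmative flag; NA (missing data) and False
    both fail, but callers can distinguish them upstream."""
    if value is None:
        return False
    try:
        if pd.isna(value):
            return False
    except (TypeError, ValueError):
        pass
    return bool(value)


def _confidence(c3: bool, c4: bool, additional: bool, documented: bool,
                require_additional_for_low: bool = True) -> str:
    both = c3 and c4
    if both and (additional or not require_additional_for_low):
        return "validated" if (documented and additional) else "low"
    if additional:
        return "medium"
    return "high"


def integrate_criteria(
    cm: pd.DataFrame,
    documented_frost_years: dict[str, list[int]] | None = None,
    require_additional_for_low: bool = True,
    c3_failure_downgrades: bool = True,
) -> FrostEventTable:
    """Fold the per-site-year criterion matrix into the event table.

    ``cm`` is indexed by (site, year) with boolean columns C1, C2, C3, C4,
    C5, A1, A2 plus supporting columns (region, C4_annotations,
    win_min_station1/2, pinpoint_doy where present). Rows exist in the output
    only where the eliminatory gates C1, C2 and C5 all hold. A failed C3 is
    annotated ``EG`` (evergreen-control reduction); with
    ``c3_failure_downgrades=False`` it annotates without affecting the level.
    """
    documented = documented_frost_years or {}
    rows = []
    for (site, year), row in cm.iterrows():
        if not (_is_true(row.get("C1")) and _is_true(row.get("C2"))
                and _is_true(row.get("C5"))):
            continue
        region = row.get("region", "")
        additional = _is_true(row.get("A1")) or _is_true(row.get("A2"))
        c3 = _is_true(row.get("C3"))
        c4 = _is_true(row.get("C4"))
        is_doc = int(year) in set(documented.get(region, []))
        level = _confidence(c3 if c3_failure_downgrades else True, c4,
                            additional, is_doc, require_additional_for_low)
        drivers = []
        if not c3:
            drivers.append("EG")
        ann = row.get("C4_annotations", "")
        if isinstance(ann, str) and ann:
            drivers.append(ann)
        rows.append({
            "region": region,
            "site": site,
            "year": int(year),
            "confidence": level,
            "window_min_station1": row.get("win_min_station1", np.nan),
            "window_min_station2": row.get("win_min_station2", np.nan),
            "co_drivers": ";".join(drivers),
            "pinpoint_doy": row.get("pinpoint_doy", pd.NA),
        })
    frame = pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)
    if len(frame):
        frame["confidence"] = pd.Categorical(frame["confidence"],
                                             categories=CONFIDENCE_ORDER,
                                             ordered=True)
        frame = frame.sort_values(["region", "year", "site"]).reset_index(drop=True)
        frame["confidence"] = frame["confidence"].astype(str)
    frame["pinpoint_doy"] = frame["pinpoint_doy"].astype("Int64")
    return FrostEventTable(frame=frame)


# --------------------------------------------------------------------------
# End-to-end orchestration


@dataclass
class ReconstructionResult:
    events: FrostEventTable
    criteria: pd.DataFrame  # full (site, year) criterion matrix
    site_chronologies: dict[str, SiteChronology]
    control_chronologies: dict[str, pd.Series]  # region -> control regional index
    regional_climate: dict[str, _climate.RegionalClimate]
    skipped: list[str] = field(default_factory=list)

    def report(self) -> str:
        lines = ["Frost event reconstruction report", "=" * 34, ""]
        if len(self.events.frame) == 0:
            lines.append("No site-year passed the eliminatory criteria.")
        for _, r in self.events.frame.iterrows():
            doy = f", DOY {r.pinpoint_doy}" if pd.notna(r.pinpoint_doy) else ""
            drv = f"; co-drivers: {r.co_drivers}" if r.co_drivers else ""
            lines.append(
                f"{r.region} {r.site} {r.year}: {r.confidence}"
                f" (window min {r.window_min_station1}/"
                f"{r.window_min_station2} degC{doy}){drv}"
            )
        if self.skipped:
            lines += ["", "Skipped site-years:"] + [f"  {s}" for s in self.skipped]
        return "\n".join(lines)


def _control_regional_index(
    control_sets: dict[str, RingWidthSet], site_codes: list[str],
    spline_length: float,
) -> pd.Series:
    chrons = []
    for code in site_codes:
        chrons.append(build_site_chronology(control_sets[code],
                                            spline_length=spline_length,
                                            compute_stats=False))
    if len(chrons) == 1:
        return chrons[0].index
    return build_regional_chronology(chrons, region="control").index


def reconstruct_events(
    target_sets: dict[str, RingWidthSet],
    control_sets: dict[str, RingWidthSet],
    stations: dict[str, list[StationDaily]],
    monthly: dict[str, dict[str, MonthlySeries]],
    config: DetectionConfig,
    spline_length: float = 50.0,
) -> ReconstructionResult:
    """Run the full detection pipeline and return events plus diagnostics.

    Inputs: per-site ring-width sets for the deciduous target network and the
    evergreen control network, two daily stations and monthly climate per
    region, and the configuration (region membership, reference periods,
    thresholds, outbreak and documented-frost year lists).
    """
    for region in config.regions:
        for code in config.regions[region]:
            if code not in target_sets:
                raise ValueError(f"config references unknown target site {code}")
    skipped: list[str] = []

    site_chrons = {code: build_site_chronology(target_sets[code],
                                               spline_length=spline_length)
                   for codes in config.regions.values() for code in codes}

    control_idx: dict[str, pd.Series] = {}
    for region, codes in config.control_regions.items():
        missing = [c for c in codes if c not in control_sets]
        if missing:
            raise ValueError(f"config references unknown control sites {missing}")
        control_idx[region] = _control_regional_index(control_sets, codes,
                                                      spline_length)

    regional_climate: dict[str, _climate.RegionalClimate] = {}
    records = []
    for region, site_codes in config.regions.items():
        region_stations = stations[region]
        yr0 = max(s.frame.index[0].year for s in region_stations)
        yr1 = min(s.frame.index[-1].year for s in region_stations)
        clim_years = range(yr0, yr1 + 1)
        rclim = _climate.build_regional_climate(
            region, region_stations, clim_years,
            cold_window=config.cold_window, warm_window=config.warm_window,
            ref_period=config.daily_ref_period,
            coverage_threshold=config.coverage_threshold,
        )
        regional_climate[region] = rclim

        c3z = zscore_ref(control_idx[region], config.c34_ref_period) \
            if region in control_idx else None

        region_chrons = [site_chrons[c] for c in site_codes]
        outbreaks = set(config.outbreak_years.get(region, []))

        for code in site_codes:
            chron = site_chrons[code]
            regional = build_regional_chronology(region_chrons, region=region,
                                                 exclude=code)
            try:
                c1 = local_growth_reductions(
                    chron, regional, threshold=config.local_reduction_sd,
                    ref_period=config.c1_ref_period)
            except ValueError as exc:
                skipped.append(f"{code}: C1 not evaluable ({exc})")
                continue

            profile = _gc.correlate_growth_climate(chron, monthly[region])
            profile = _gc.select_key_variables(
                profile, alpha=config.correlation_alpha,
                fallback=config.fallback_key_variables.get(region))
            if profile.key_variables:
                c4 = _gc.climate_deviation_flags(
                    monthly[region], profile, chron.index.dropna().index,
                    threshold=config.climate_deviation_sd,
                    ref_period=config.c34_ref_period,
                    two_sided=config.two_sided_deviations)
            else:
                c4 = None
                skipped.append(f"{code}: no key climate variables, C4 skipped")

            crop = cropper_values(chron.series_indices)
            a1 = pointer_years(crop, value_threshold=config.cropper_threshold,
                               proportion=config.pointer_proportion,
                               min_series=config.pointer_min_series)

            for year in chron.index.dropna().index:
                year = int(year)
                if year not in rclim.table.index:
                    continue
                cl = rclim.table.loc[year]
                if bool(cl["excluded"]):
                    if c1.at[year, "flag"]:
                        skipped.append(f"{code} {year}: daily coverage inadequate")
                    continue
                rec = {
                    "site": code, "year": year, "region": region,
                    "C1": bool(c1.at[year, "flag"]),
                    "C1_z": c1.at[year, "z"],
                    "C2": bool(cl["win_min_z"] < config.cold_z),
                    "C2_z": cl["win_min_z"],
                    "C5": year not in outbreaks,
                    "A2": bool(np.isfinite(cl["FR_z"]) and cl["FR_z"] > config.fr_z),
                    "A2_z": cl["FR_z"],
                    "win_min_station1": cl[f"win_min_{rclim.stations[0]}"],
                    "win_min_station2": cl[f"win_min_{rclim.stations[1]}"],
                }
                if c3z is not None and year in c3z.index and np.isfinite(c3z.at[year]):
                    rec["C3"] = bool(c3z.at[year] >= -config.control_sd)
                    rec["C3_z"] = c3z.at[year]
                else:
                    rec["C3"] = pd.NA
                    rec["C3_z"] = np.nan
                if c4 is not None and year in c4.index:
                    rec["C4"] = bool(c4.at[year, "c4_ok"])
                    rec["C4_annotations"] = c4.at[year, "annotations"]
                else:
                    rec["C4"] = pd.NA
                    rec["C4_annotations"] = ""
                if year in a1.index and bool(a1.at[year, "evaluable"]):
                    rec["A1"] = bool(a1.at[year, "flag"])
                    rec["A1_fraction"] = a1.at[year, "fraction"]
                else:
                    rec["A1"] = False
                    rec["A1_fraction"] = np.nan
                    if year in a1.index and c1.at[year, "flag"]:
                        skipped.append(f"{code} {year}: pointer test not evaluable "
                                       f"(<{config.pointer_min_series} series)")
                records.append(rec)

    cm = pd.DataFrame.from_records(records).set_index(["site", "year"]) \
        if records else pd.DataFrame(columns=["site", "year"]).set_index(["site", "year"])

    events = integrate_criteria(
        cm, config.documented_frost_years,
        require_additional_for_low=config.require_additional_for_low,
        c3_failure_downgrades=config.c3_failure_downgrades,
    )

    # pinpoint the frost day for low-uncertainty and validated events
    frame = events.frame
    for i, r in frame.iterrows():
        if r["confidence"] not in ("low", "validated"):
            continue
        comp = _climate.regional_daily(stations[r["region"]])
        try:
            hit = _climate.pinpoint_frost_day(comp, int(r["year"]),
                                              window=config.pinpoint_window)
        except ValueError:
            continue
        if hit is not None:
            frame.at[i, "pinpoint_doy"] = hit[0]
    frame["pinpoint_doy"] = frame["pinpoint_doy"].astype("Int64")

    return ReconstructionResult(
        events=events, criteria=cm, site_chronologies=site_chrons,
        control_chronologies=control_idx, regional_climate=regional_climate,
        skipped=skipped,
    )
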