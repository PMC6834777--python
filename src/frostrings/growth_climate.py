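"""Monthly growth-climate screening and adverse-deviation flags.

Site chronologies are correlated (Pearson) with monthly mean temperature and
precipitation over a 15-month window running from January of the year the
ring forms (its growing season starts in the austral spring of that year)
through March of the following calendar year. Variables significantly
correlated with growth (p < alpha, strict) become that site's *key
variables*; a year then counts as climatically clean only when no key
variable deviates beyond the threshold in the direction opposite its growth
correlation (e.g. anomalously wet Decembers where December precipitation
correlates negatively with growth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .chronology import SiteChronology
from .data_io import MonthlySeries

MIN_OVERLAP = 20

_MONTH_TOKENS = ["jan", "feb", "mar", "apr", "may", "jun", "jul", "aug",
                 "sep", "oct", "nov", "dec"]
#: 15 month-lags: Jan..Dec of ring year t, then Jan..Mar of year t+1.
MONTH_LAGS = _MONTH_TOKENS + ["jan+1", "feb+1", "mar+1"]


def _lag_to_year_month(token: str) -> tuple[int, int]:
    """(year offset relative to ring year, calendar month) for a lag token."""
    if token.endswith("+1"):
        return 1, _MONTH_TOKENS.index(token[:-2]) + 1
    return 0, _MONTH_TOKENS.index(token) + 1


def monthly_at_lag(monthly: MonthlySeries, years: np.ndarray, lag: str) -> pd.Series:
    """Monthly values aligned to ring years for one month-lag."""
    offset, month = _lag_to_year_month(lag)
    vals = {}
    for y in years:
        vals[y] = monthly.values.get((y + offset, month), np.nan)
    return pd.Series(vals, dtype=float)


@dataclass
class ClimateGrowthProfile:
    site_code: str
    table: pd.DataFrame  # index "variable:lag", columns r, p, n
    key_variables: list[str] = field(default_factory=list)
    fallback: bool = False


def correlate_growth_climate(
    chron: SiteChronology,
    monthly: dict[str, MonthlySeries],
    period: tuple[int, int] | None = None,
) -> ClimateGrowthProfile:
    """Pearson r and two-sided p for every (variable, month-lag) pair.

    ``monthly`` maps variable names (``temperature``, ``precipitation``) to
    their series. Requires at least 20 overlapping years per pair; p-values
    use the t approximation, uncorrected for multiple testing.
    """
    idx = chron.index.dropna()
    rows = {}
    for var, series in monthly.items():
        for lag in MONTH_LAGS:
            clim = monthly_at_lag(series, idx.index.to_numpy(), lag)
            pair = pd.DataFrame({"g": idx, "c": clim}).dropna()
            if period is not None:
                pair = pair.loc[(pair.index >= period[0]) & (pair.index <= period[1])]
            n = len(pair)
            if n < MIN_OVERLAP:
                raise ValueError(
                    f"{chron.site_code}: only {n} overlapping years for "
                    f"{var}:{lag} (need >= {MIN_OVERLAP})"
                )
            if pair["c"].std() == 0 or pair["g"].std() == 0:
                rows[f"{var}:{lag}"] = (np.nan, np.nan, n)
                continue
            r, p = sstats.pearsonr(pair["g"], pair["c"])
            rows[f"{var}:{lag}"] = (r, p, n)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p", "n"])
    return ClimateGrowthProfile(site_code=chron.site_code, table=table)


def select_key_variables(
    profile: ClimateGrowthProfile,
    alpha: float = 0.01,
    fallback: list[str] | None = None,
) -> ClimateGrowthProfile:
    """Keep (variable, lag) pairs with p strictly below alpha; when none
    qualifies, fall back to the region's default set (flagged)."""
    selected = profile.table.index[profile.table["p"] < alpha].tolist()
    if selected:
        profile.key_variables = selected
        profile.fallback = False
    else:
        profile.key_variables = list(fallback or [])
        profile.fallback = True
    return profile


_LABELS = {"temperature": "T", "precipitation": "P"}


def _annotation(key: str, high: bool) -> str:
    var, lag = key.split(":")
    letter = _LABELS.get(var, var[:1].upper())
    return f"{'high' if high else 'low'} {letter}-{lag.capitalize()}"


def climate_deviation_flags(
    monthly: dict[str, MonthlySeries],
    profile: ClimateGrowthProfile,
    years: np.ndarray | list[int],
    threshold: float = 1.0,
    ref_period: tuple[int, int] = (1950, 2003),
    two_sided: bool = False,
) -> pd.DataFrame:
    """Adverse-deviation annotations per year for a site's key variables.

    Each key variable is z-scored over the reference period; a year is
    flagged *adverse* when the z-score strictly exceeds the threshold in the
    direction opposite the sign of the variable's growth correlation (a
    favourable deviation cannot explain a growth reduction). The year passes
    the clean-climate criterion iff no key variable is adverse.

    Returns a year-indexed frame with ``c4_ok`` and ``annotations``
    (semicolon-joined labels such as ``high P-Dec``).
    """
    if not profile.key_variables:
        raise ValueError("no key variables (supply a fallback set)")
    years = np.asarray(list(years))
    annotations: dict[int, list[str]] = {int(y): [] for y in years}
    for key in profile.key_variables:
        var, lag = key.split(":")
        series = monthly_at_lag(monthly[var], years, lag)
        lo, hi = ref_period
        ref = monthly_at_lag(monthly[var], np.arange(lo, hi + 1), lag).dropna()
        if len(ref) < 2:
            raise ValueError(f"{key}: <2 reference years in {lo}-{hi}")
        sd = ref.std(ddof=1)
        if sd == 0:
            raise ValueError(f"{key}: zero variance over {lo}-{hi}")
        z = (series - ref.mean()) / sd
        r = profile.table.at[key, "r"] if key in profile.table.index else np.nan
        sign = np.sign(r) if np.isfinite(r) else 0.0
        for y in years:
            zy = z.get(int(y), np.nan)
            if not np.isfinite(zy):
                continue
            if two_sided or sign == 0:
                adverse = abs(zy) > threshold
                high = zy > 0
            elif sign < 0:
                adverse, high = zy > threshold, True
            else:
                adverse, high = zy < -threshold, False
            if adverse:
                annotations[int(y)].append(_annotation(key, high))
    out = pd.DataFrame(index=pd.Index(years.astype(int), name="year"))
    out["annotations"] = [";".join(annotations[int(y)]) for y in years]
    out["c4_ok"] = out["annotations"] == ""
    return out
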