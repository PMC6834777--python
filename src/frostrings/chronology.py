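"""Site and regional residual chronologies from raw ring widths.

The standardization follows the classical dendrochronological sequence:

1. a negative exponential ``w = a*exp(-b*t) + c`` (a, b > 0) is fitted to each
   core and the widths divided by it, removing the ontogenetic juvenile
   trend (fallback: the horizontal mean, when the fit fails or is
   non-decreasing);
2. a cubic smoothing spline whose frequency response is 50% at the cutoff
   period (50 years by default) is fitted to the step-1 ratios and divided
   out, removing medium-frequency disturbance signals;
3. the ratio series is prewhitened with an AR(p) model (p chosen by AIC,
   p <= 10) and the series mean re-added, so residual indices stay centered
   near 1;
4. per-year indices are averaged across cores with Tukey's biweight robust
   mean, weighted down-sampling outliers.

Quality statistics (mean sensitivity, first-order autocorrelation, mean
inter-series correlations rbt/rbar and the expressed population signal EPS)
quantify the shared high-frequency signal of the resulting chronology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit
from sklearn.decomposition import PCA

from .data_io import RingWidthSet
from .util import biweight_mean

logger = logging.getLogger(__name__)

MIN_SERIES_LENGTH = 15
MIN_PAIR_OVERLAP = 20


@dataclass
class ChronologyStats:
    MS: float
    AC1: float
    rbt: float  # mean inter-series correlation of raw widths
    rbar: float  # mean inter-series correlation of residual indices
    EPS: float
    N: float  # mean sample depth


@dataclass
class SiteChronology:
    site_code: str
    index: pd.Series  # year-indexed residual chronology, centered near 1
    sample_depth: pd.Series
    stats: ChronologyStats | None = None
    series_indices: pd.DataFrame | None = None  # year x core residual indices

    @property
    def years(self) -> np.ndarray:
        return self.index.index.to_numpy()


@dataclass
class RegionalChronology:
    region: str
    index: pd.Series
    contributing_sites: list[str] = field(default_factory=list)
    excluded_site: str | None = None


# --------------------------------------------------------------------------
# Detrending primitives


def _negexp_curve(widths: np.ndarray) -> np.ndarray:
    """Fitted negative-exponential age curve, or the horizontal mean when the
    fit fails, is non-decreasing, or dips to non-positive values."""
    n = widths.size
    t = np.arange(n, dtype=float)
    mean = widths.mean()
    if mean <= 0:
        raise ValueError("series mean width must be positive")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda tt, a, b, c: a * np.exp(-b * tt) + c,
                t,
                widths,
                p0=(max(widths[0] - widths[-1], 0.1 * mean), 0.05, widths[-1]),
                maxfev=2000,
            )
        a, b, c = popt
        if a <= 0 or b <= 0:
            raise RuntimeError("non-decreasing fit")
        curve = a * np.exp(-b * t) + c
        if np.any(curve <= 0):
            raise RuntimeError("curve crosses zero")
        return curve
    except (RuntimeError, ValueError):
        return np.full(n, mean)


def spline_smoothing_lambda(cutoff: float, f: float = 0.5) -> float:
    """Roughness penalty giving a smoothing-spline frequency response of
    ``f`` at period ``cutoff`` (unit-spaced samples)."""
    theta = 2.0 * np.pi / cutoff
    return ((np.cos(theta) + 2.0) * (1.0 - f)) / (12.0 * f * (np.cos(theta) - 1.0) ** 2)


def smoothing_spline(y: np.ndarray, cutoff: float, f: float = 0.5) -> np.ndarray:
    """Cubic smoothing spline with 100*f% frequency response at ``cutoff``."""
    x = np.arange(y.size, dtype=float)
    lam = spline_smoothing_lambda(cutoff, f)
    return make_smoothing_spline(x, np.asarray(y, float), lam=lam)(x)


def _prewhiten(index: np.ndarray, max_order: int = 10) -> np.ndarray:
    """AR(p) residuals (p by AIC, p <= max_order) re-centered on the series
    mean; the first p years, which have no residual, become NaN. A series
    with (near) zero variance is returned unchanged."""
    from statsmodels.tsa.ar_model import AutoReg, ar_select_order

    x = np.asarray(index, float)
    if x.std() < 1e-10 or x.size < 10:
        return x.copy()
    maxlag = int(min(max_order, x.size // 3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = ar_select_order(x, maxlag=maxlag, ic="aic", trend="c")
    lags = sel.ar_lags or []
    if not lags:
        return x.copy()
    p = max(lags)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = AutoReg(x, lags=lags, trend="c").fit()
    out = np.full(x.size, np.nan)
    out[p:] = res.resid + x.mean()
    return out


def detrend_series(
    widths: np.ndarray, spline_length: float = 50.0, prewhiten: bool = True
) -> np.ndarray:
    """Two-step ratio detrending plus optional AR prewhitening of one core."""
    curve1 = _negexp_curve(np.asarray(widths, float))
    ratio1 = widths / curve1
    curve2 = smoothing_spline(ratio1, cutoff=spline_length)
    curve2 = np.where(curve2 <= 0, np.nan, curve2)
    ratio2 = ratio1 / curve2
    if not prewhiten:
        return ratio2
    return _prewhiten(ratio2)


# --------------------------------------------------------------------------
# Chronology assembly


def build_site_chronology(
    rw: RingWidthSet,
    spline_length: float = 50.0,
    prewhiten: bool = True,
    compute_stats: bool = True,
) -> SiteChronology:
    """Detrend every core of a site and average the residual indices into a
    chronology with Tukey's biweight mean.

    Cores shorter than 15 years are skipped with a warning; an empty or
    all-short collection raises.
    """
    usable = {}
    for cid, s in rw.series.items():
        if s.widths.size < MIN_SERIES_LENGTH:
            logger.warning(
                "site %s: series %s shorter than %d years, skipped",
                rw.site_code, cid, MIN_SERIES_LENGTH,
            )
            continue
        usable[cid] = s
    if not usable:
        raise ValueError(f"site {rw.site_code}: no series of usable length")

    first = min(s.first_year for s in usable.values())
    last = max(s.last_year for s in usable.values())
    idx = pd.RangeIndex(first, last + 1, name="year")
    mat = pd.DataFrame(index=idx, columns=list(usable), dtype=float)
    for cid, s in usable.items():
        mat.loc[s.years, cid] = detrend_series(
            s.widths, spline_length=spline_length, prewhiten=prewhiten
        )

    depth = mat.notna().sum(axis=1)
    chron = mat.apply(lambda row: biweight_mean(row.to_numpy()), axis=1)
    chron[depth == 0] = np.nan

    stats = None
    if compute_stats:
        try:
            stats = chronology_stats(rw, mat)
        except ValueError:
            stats = None
    return SiteChronology(
        site_code=rw.site_code,
        index=chron,
        sample_depth=depth,
        stats=stats,
        series_indices=mat,
    )


def _mean_pairwise_r(frame: pd.DataFrame, min_overlap: int = MIN_PAIR_OVERLAP) -> float:
    cols = frame.columns
    rs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair = frame[[cols[i], cols[j]]].dropna()
            if len(pair) < min_overlap:
                continue
            a, b = pair.iloc[:, 0], pair.iloc[:, 1]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(a.corr(b))
    return float(np.mean(rs)) if rs else np.nan


def eps(rbar: float, n: float) -> float:
    """Expressed population signal: EPS = N*rbar / (N*rbar + (1 - rbar))."""
    if not np.isfinite(rbar) or not np.isfinite(n):
        return np.nan
    denom = n * rbar + (1.0 - rbar)
    return float(n * rbar / denom) if denom > 0 else np.nan


def chronology_stats(rw: RingWidthSet, indices: pd.DataFrame) -> ChronologyStats:
    """Quality statistics of a site collection.

    MS and AC1 are computed on the raw widths (per-series, then averaged);
    rbt on raw-width pairs and rbar on residual-index pairs, both over
    overlaps of at least 20 years; EPS from rbar and the mean sample depth.
    With fewer than two series the inter-series statistics are NaN
    (undefined), never zero.
    """
    raw = rw.to_frame()
    ms_vals, ac_vals = [], []
    for cid in raw.columns:
        x = raw[cid].dropna().to_numpy()
        if x.size < 2:
            continue
        s = x[1:] + x[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(s > 0, 2.0 * np.abs(np.diff(x)) / s, 0.0)
        ms_vals.append(terms.mean())
        if np.std(x[1:]) > 0 and np.std(x[:-1]) > 0:
            ac_vals.append(float(np.corrcoef(x[1:], x[:-1])[0, 1]))
    if not ms_vals:
        raise ValueError("need at least one series with >= 2 years")

    if raw.shape[1] >= 2:
        rbt = _mean_pairwise_r(raw)
        rbar = _mean_pairwise_r(indices)
    else:
        rbt = rbar = np.nan
    n_mean = float(indices.notna().sum(axis=1).replace(0, np.nan).dropna().mean())
    return ChronologyStats(
        MS=float(np.mean(ms_vals)),
        AC1=float(np.mean(ac_vals)) if ac_vals else np.nan,
        rbt=rbt,
        rbar=rbar,
        EPS=eps(rbar, n_mean),
        N=n_mean,
    )


def build_regional_chronology(
    chronologies: dict[str, SiteChronology] | list[SiteChronology],
    region: str = "",
    exclude: str | None = None,
) -> RegionalChronology:
    """Arithmetic mean of site chronologies per year, over the sites present
    that year; the excluded site's data contributes nothing anywhere.

    The leave-one-out variant is the reference against which local growth
    reductions are judged, so the exclusion must be total.
    """
    if isinstance(chronologies, dict):
        chron_list = list(chronologies.values())
    else:
        chron_list = list(chronologies)
    kept = [c for c in chron_list if c.site_code != exclude]
    min_needed = 2
    if len(kept) < min_needed:
        raise ValueError(
            f"region {region!r}: need >= {min_needed} site chronologies"
            + (f" after excluding {exclude}" if exclude else "")
        )
    mat = pd.concat({c.site_code: c.index for c in kept}, axis=1)
    return RegionalChronology(
        region=region,
        index=mat.mean(axis=1, skipna=True),
        contributing_sites=[c.site_code for c in kept],
        excluded_site=exclude,
    )


def pca_regions(
    chronologies: dict[str, SiteChronology],
    climate_profiles: pd.DataFrame | None = None,
    period: tuple[int, int] | None = None,
) -> dict:
    """Exploratory PCA over site chronologies (and optionally growth-climate
    correlation profiles) for grouping sites into homogeneous regions.

    Region membership remains a configuration input — the PCA only informs
    the analyst's choice. Returns scores, loadings and explained variance
    for the chronology PCA, plus the same for the profile PCA when profiles
    are given (rows = sites, columns = correlation coefficients).
    """
    mat = pd.concat({code: c.index for code, c in chronologies.items()}, axis=1)
    if period is not None:
        mat = mat.loc[(mat.index >= period[0]) & (mat.index <= period[1])]
    mat = mat.dropna()
    if len(mat) < 10:
        raise ValueError("common period across sites is shorter than 10 years")
    std = (mat - mat.mean()) / mat.std(ddof=1)
    n_comp = min(std.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(std.to_numpy())
    out = {
        "scores": pd.DataFrame(scores, index=mat.index,
                               columns=[f"PC{i+1}" for i in range(n_comp)]),
        "loadings": pd.DataFrame(pca.components_.T, index=mat.columns,
                                 columns=[f"PC{i+1}" for i in range(n_comp)]),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
    if climate_profiles is not None:
        prof = climate_profiles.dropna(axis=1)
        k = min(prof.shape)
        p2 = PCA(n_components=k)
        sc2 = p2.fit_transform(prof.to_numpy())
        out["profile_scores"] = pd.DataFrame(
            sc2, index=prof.index, columns=[f"PC{i+1}" for i in range(k)]
        )
        out["profile_explained_variance_ratio"] = p2.explained_variance_ratio_
    return out
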