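"""Shared numerical helpers: reference-period standardization and the
Tukey biweight robust mean."""

from __future__ import annotations

import numpy as np
import pandas as pd


def zscore_ref(series: pd.Series, ref_period: tuple[int, int]) -> pd.Series:
    """Standardize a year-indexed series by the mean/SD of a reference period.

    Only reference years actually present (non-NaN) enter the mean and SD;
    the SD uses ddof=1. A degenerate reference (SD == 0 or < 2 usable years)
    raises, because a z-score against it is meaningless.
    """
    lo, hi = ref_period
    ref = series.loc[(series.index >= lo) & (series.index <= hi)].dropna()
    if len(ref) < 2:
        raise ValueError(f"reference period {lo}-{hi}: <2 usable years")
    sd = ref.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"reference period {lo}-{hi}: zero variance")
    return (series - ref.mean()) / sd


def biweight_mean(values: np.ndarray, c: float = 9.0, n_iter: int = 10) -> float:
    """Tukey's biweight robust location estimate.

    Distances are scaled by ``c`` times the median absolute deviation and
    re-weighted by (1-u^2)^2 for |u| < 1 over ``n_iter`` iterations. With
    three or fewer values (or zero MAD) the arithmetic mean is returned:
    robust weighting is not identifiable at that sample size.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan
    if x.size <= 3:
        return float(x.mean())
    m = float(np.median(x))
    for _ in range(n_iter):
        mad = float(np.median(np.abs(x - m)))
        if mad == 0:
            return float(x.mean()) if np.ptp(x) == 0 else m
        u = (x - m) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m = float(np.sum(w * x) / w.sum())
    return m
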