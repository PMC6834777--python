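# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `frostrings`, and what the synthetic tests do and do not
demonstrate about real data.

## Chronology construction

Each core is detrended by sequential ratios: first a negative exponential
`w(t) = a·e^(−bt) + c` fitted by nonlinear least squares (constraints
a, b > 0; fallback to the horizontal mean when the fit fails, is
non-decreasing, or the fitted curve crosses zero — the conservative
standard fallback), then a cubic smoothing spline fitted to the step-1
ratios and divided out. The spline's roughness penalty is chosen so its
frequency response is 0.5 at the cutoff period (50 years by default):
λ = (cos θ + 2)(1 − f) / (12 f (cos θ − 1)²) with θ = 2π/cutoff and
f = 0.5, passed to a standard smoothing-spline solver. The implementation
is verified numerically on sinusoids (measured gain 0.500 at the 50-year
period, 0.94 at 100, 0.03 at 20), i.e. the spline passes decadal-scale
variance and removes century-scale trend.

Prewhitening fits an AR(p) model with p ≤ 10 selected by AIC and keeps the
residuals, re-centered by adding the series mean, so indices stay near 1;
the first p years have no residual and are left undefined. Series with
near-zero variance skip the AR step (the fit is degenerate and the series
already carries no autocorrelation structure). Cores shorter than 15 years
are skipped with a warning.

Per-year averaging uses Tukey's biweight (c = 9 × MAD, 10 iterations),
falling back to the arithmetic mean for ≤ 3 values, where robust weighting
is not identifiable. Inter-series correlations (rbt on raw widths, rbar on
residual indices) require ≥ 20 overlapping years per pair; with fewer than
two series they are reported as undefined (NaN), never as zero. EPS uses
the closed form N·r̄/(N·r̄ + 1 − r̄) with N the mean sample depth.

The regional reference is the unweighted arithmetic mean of site
chronologies over the sites present each year; the leave-one-out variant
omits the target site entirely, which the tests verify by perturbing the
excluded site arbitrarily.

## Climate indices

Criterion 2 standardizes *annual window minima* across years rather than
z-scoring daily values: day-level z-scores would be dominated by the
seasonal cycle, and the quantity of interest is the severity of the coldest
night of the leaf-unfolding window. The two-station regional composite
averages per-station z-scores (not z of averaged temperatures), so a
station with larger variance does not dominate. Years in which a station
covers less than 90 % of the window days are excluded, never filled.

Window conventions: all windows are inclusive on both ends; the "first
fortnight of November" is Nov 1–15. The frost-risk index is computed per
station as mean(Tmean, Sep 15–Oct 15) − min(Tmin, Oct 1–Nov 15), averaged
across stations, and standardized over the daily reference period. FR is
exactly invariant to adding a constant to all temperatures and monotone
under lowering any cold-window minimum; both properties are tested to
machine precision.

The frost-day pinpoint searches Oct 1–Nov 30 (extended past Nov 15 to
capture early-November damage dates) and requires a complete 10-day Tmean
history before each candidate day; ties break to the earliest day, and a
maximum amplitude ≤ 0 means "no frost signature".

## Growth–climate screening and adverse deviations

Monthly temperature and precipitation are screened over 15 month-lags,
January of the ring year through March of the following calendar year
(under the Southern Hemisphere convention the ring year is the calendar
year in which growth begins, so the "current" Jan–Mar fall in year t+1).
P-values use the t approximation and no multiple-testing correction — the
screen is deliberately permissive because the selected variables gate a
conservative exclusion criterion, not an inference. With no variable at
p < 0.01 a configured regional default set is used and flagged.

Adverse deviations are one-sided: a deviation only counts against a year
when it points opposite the variable's growth correlation (a wet November
cannot explain a growth reduction at a site where November rain aids
growth). The event-table annotations ("high P-Dec", "low T-Nov") follow
this direction. A config switch (`two_sided_deviations`) restores the
symmetric reading.

## Criteria integration

All thresholds are strict inequalities (z = −1.5 exactly does not flag; 5
of 10 series is not a pointer year); the boundary cases are pinned by
tests. The level lattice is: gates C1 ∧ C2 ∧ C5 admit a row; *low*
additionally requires C3 ∧ C4 and one of A1/A2; *medium* requires one of
A1/A2 with C3 ∧ C4 failing (failures annotated as co-drivers); *validated*
adds a documented record. Two deliberately exposed policy switches cover
genuinely ambiguous readings of the scale: `require_additional_for_low`
(default on: low uncertainty needs a pointer year or high FR) and
`c3_failure_downgrades` (default on: a control-species reduction downgrades
rather than merely annotates). Confidence is monotone in every criterion —
switching any criterion from fail to pass never lowers a level — which is
verified over the full combinatorial space.

Pointer years need ≥ 5 series present; below that A1 is "not evaluable",
which counts as not-met for leveling and is logged. Cropper values use the
sample SD (ddof = 1) in the 5-year window, truncated at the series edges;
zero-SD windows give 0.

## Synthetic data: what it emulates and what it does not

Widths compose multiplicatively:
`width = ageCurve × exp(regional + site + tree + core) × eventFactor`, with
the age curve a per-tree negative exponential (a ∈ [0.5, 2] mm,
b ∈ [0.02, 0.08] yr⁻¹, c ∈ [0.3, 0.8] mm), tree noise AR(1) with φ = 0.3,
and log-scale SDs 0.12/0.08/0.15/0.05 (regional/site/tree/core). Half of
the regional signal variance (coupling 0.5) is driven by the standardized
Nov–Dec composite temperature of the region's stations, so the
growth–climate screen finds real structure. Daily stations share a regional
AR(1) anomaly (SD 2 °C, coefficient 0.7) plus station-specific anomalies
(SD 1 °C) on a seasonal cycle (mean 8 °C, amplitude 7 °C, warmest mid
January); Tmin sits a 6 °C diurnal offset below Tmean with bounded noise.
Monthly temperature is the exact calendar aggregate of the daily composite;
precipitation is an independent seasonal gamma (winter-wet). The defaults
describe a scaled-down network (15 trees × 2 cores per site) chosen to keep
a full pipeline run on one CPU in tens of seconds while leaving sample
depths in the range where EPS ≈ 0.95+.

Injected frosts multiply the affected deciduous sites by (1 − reduction)
in the event year and write a warm spell followed by a 1–3 day cold snap
into the daily series, the snap minimum placed `cold_snap_sd` SD below the
pre-injection climatology of window minima. Droughts multiply every site of
the region in both networks. Frost years are generated as *climatically
ordinary* apart from the injected episode: the weather anomaly is shrunk by
`event_damp` = 0.25 and precipitation set to its seasonal mean over the
full Jan(t)–Mar(t+1) attribution window. This is a property of the ground
truth, not a convenience: an injected "pure frost" that randomly coincided
with a monthly climate anomaly would be a mixed event and its truth-table
label wrong. Events without a preceding warm spell can be generated
(`with_warm_spell=False`) to exercise the frost-without-warm-spring case,
which can at best reach medium confidence through the pointer-year route.

What passing tests do **not** show about real data: the generator has no
missing rings, no dating errors, no elevation lapse between station and
forest, no spatial gradients within a region, full station coverage, and
stationary noise; real chronologies violate all of these to some degree.
The recovery and false-positive rates measured on synthetic networks
characterize the procedure under its own assumptions, not field
performance.

## Problem sizes and numerics

The acceptance script runs the 2-region × 6-site × 15-tree × 80-year
design (six frosts, four droughts) for recovery metrics and ten seeded
no-event 2 × 4 × 8 × 80 networks (≈ 6 300 site-years) for the
spurious-detection rate; these sizes keep a complete run around two
minutes on one CPU. Oracle comparisons (Cropper, pinpoint, EPS, FR
invariance) agree with exhaustive brute-force implementations at
≤ 1e-12. Reference-period z-scores use ddof = 1 and raise on degenerate
references (zero variance, < 2 years — < 5 for daily indices) rather than
silently emitting infinities.

## Known limitations

- The negative-exponential fit is unconstrained beyond a, b > 0; for
  strongly non-monotone juvenile growth the horizontal-mean fallback can
  under-remove trend (mitigated by the spline step).
- Criterion 3 uses the control network's own regional mean, not a
  leave-one-out, since target sites are absent from the control network;
  a sparse control network (one site) degrades to that site's chronology.
- The pointer-year test needs per-series indices, so it is only evaluable
  where the site has ≥ 5 live series; early chronology ends lose A1.
- Monthly climate enters only through Pearson screening; nonlinear or
  lagged-beyond-15-months responses are out of scope.
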