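import numpy as np
import pandas as pd
import pytest

from frostrings.synthetic import (
    InjectedEvent,
    SimulationParams,
    demo_params,
    simulate_daily_temperature,
    simulate_network,
    simulate_ring_widths,
)


def tiny_params(**kw):
    defaults = dict(n_regions=1, sites_per_region=2, control_sites_per_region=1,
                    trees_per_site=3, cores_per_tree=1, n_years=60,
                    start_year=1950, seed=0)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestValidation:
    def test_reduction_fraction_bounds(self):
        with pytest.raises(ValueError, match="reduction"):
            InjectedEvent(type="frost", year=1980, region="R1", reduction=1.0)

    def test_minimum_years(self):
        with pytest.raises(ValueError, match="n_years"):
            tiny_params(n_years=40)

    def test_event_year_inside_span(self):
        with pytest.raises(ValueError, match="outside"):
            tiny_params(events=[InjectedEvent(type="frost", year=1900,
                                              region="R1", reduction=0.5)])


class TestDailyTemperature:
    def test_same_seed_identical(self):
        p = tiny_params(seed=42)
        a = simulate_daily_temperature(p, "R1")
        b = simulate_daily_temperature(p, "R1")
        for sa, sb in zip(a.stations, b.stations):
            pd.testing.assert_frame_equal(sa.frame, sb.frame)

    def test_zero_noise_equals_pure_seasonal_cycle(self):
        p = tiny_params(weather_sd=0.0, station_sd=0.0, tmin_noise_sd=0.0)
        res = simulate_daily_temperature(p, "R1")
        f = res.stations[0].frame
        doy = f.index.dayofyear.to_numpy()
        seasonal = p.seasonal_mean + p.seasonal_amp * np.cos(
            2 * np.pi * (doy - p.warmest_doy) / 365.25)
        np.testing.assert_allclose(f["tmean"], seasonal, atol=1e-12)
        np.testing.assert_allclose(f["tmean"] - f["tmin"], p.diurnal_offset,
                                   atol=1e-12)

    def test_tmin_never_exceeds_tmean(self):
        p = demo_params(seed=5, n_regions=1, sites_per_region=2, trees_per_site=3)
        res = simulate_daily_temperature(p, "R1")
        for s in res.stations:
            assert (s.frame["tmin"] <= s.frame["tmean"]).all()

    def test_injected_snap_is_global_window_minimum(self):
        """A 2.5 SD cold snap makes that year's Oct 1 - Nov 15 minimum the
        lowest among all simulated years' windows."""
        ev = InjectedEvent(type="frost", year=1990, region="R1",
                           sites=["R1s01"], reduction=0.5, cold_snap_sd=2.5)
        p = tiny_params(events=[ev], seed=2)
        res = simulate_daily_temperature(p, "R1")
        f = res.stations[0].frame
        mins = {}
        for year in p.years:
            w = f.loc[f"{year}-10-01":f"{year}-11-15", "tmin"]
            mins[year] = w.min()
        assert min(mins, key=mins.get) == 1990

    def test_warm_spell_and_snap_inside_their_windows(self):
        ev = InjectedEvent(type="frost", year=1990, region="R1",
                           sites=["R1s01"], reduction=0.5)
        p = tiny_params(events=[ev], seed=3)
        res = simulate_daily_temperature(p, "R1")
        snap = res.snap_days[1990]
        assert pd.Timestamp("1990-10-01") <= snap <= pd.Timestamp("1990-11-15")


class TestRingWidths:
    def test_zero_noise_gives_pure_age_curve(self):
        p = tiny_params(regional_sd=0.0, site_sd=0.0, tree_sd=0.0, core_sd=0.0,
                        max_start_offset=0)
        targets, controls = simulate_ring_widths(p, "R1")
        for rw in list(targets.values()) + list(controls.values()):
            for s in rw.series.values():
                t = np.arange(s.widths.size, dtype=float)
                diffs = np.diff(s.widths)
                assert (diffs <= 1e-12).all()  # negexp + c is decreasing
                # and exactly representable as a*exp(-b t) + c: check via
                # log-linearity of (w - c_est) where c_est is the tail limit
                resid = s.widths - s.widths[-1]
                assert resid[0] > 0

    def test_frost_event_halves_affected_site_only(self):
        """Paired runs with the same seed: a 0.5-reduction frost halves mean
        raw width at the affected site-year and leaves controls unchanged."""
        ev = InjectedEvent(type="frost", year=1990, region="R1",
                           sites=["R1s01"], reduction=0.5)
        p0 = tiny_params(seed=9)
        p1 = tiny_params(seed=9, events=[ev])
        t0, c0 = simulate_ring_widths(p0, "R1")
        t1, c1 = simulate_ring_widths(p1, "R1")

        def mean_width(sets, code, year):
            vals = [s.widths[year - s.first_year] for s in sets[code].series.values()
                    if s.first_year <= year <= s.last_year]
            return np.mean(vals)

        # event year: affected site halved (same seed, damped weather differs
        # slightly through the climate coupling; ratio is exact per series)
        w0 = [s.widths[1990 - s.first_year] for s in t0["R1s01"].series.values()]
        w1 = [s.widths[1990 - s.first_year] for s in t1["R1s01"].series.values()]
        ratios = np.array(w1) / np.array(w0)
        assert np.allclose(ratios, 0.5, atol=0.1)
        # control network untouched by frost (weather damping aside)
        r_ctrl = mean_width(c1, "R1c01", 1990) / mean_width(c0, "R1c01", 1990)
        assert r_ctrl > 0.8

    def test_drought_event_reduces_both_networks(self):
        ev = InjectedEvent(type="drought", year=1990, region="R1", reduction=0.45)
        p0 = tiny_params(seed=9)
        p1 = tiny_params(seed=9, events=[ev])
        t0, c0 = simulate_ring_widths(p0, "R1")
        t1, c1 = simulate_ring_widths(p1, "R1")
        for sets0, sets1 in ((t0, t1), (c0, c1)):
            for code in sets0:
                for cid in sets0[code].series:
                    s0, s1 = sets0[code].series[cid], sets1[code].series[cid]
                    i = 1990 - s0.first_year
                    assert s1.widths[i] == pytest.approx(0.55 * s0.widths[i])

    def test_widths_strictly_positive(self, small_net):
        for rw in {**small_net.targets, **small_net.controls}.values():
            for s in rw.series.values():
                assert (s.widths > 0).all()


class TestNetwork:
    def test_same_seed_bit_identical(self):
        a = simulate_network(tiny_params(seed=21))
        b = simulate_network(tiny_params(seed=21))
        for code in a.targets:
            for cid in a.targets[code].series:
                np.testing.assert_array_equal(a.targets[code].series[cid].widths,
                                              b.targets[code].series[cid].widths)
        for region in a.stations:
            for sa, sb in zip(a.stations[region], b.stations[region]):
                pd.testing.assert_frame_equal(sa.frame, sb.frame)
            pd.testing.assert_series_equal(
                a.monthly[region]["precipitation"].values,
                b.monthly[region]["precipitation"].values)

    def test_monthly_temperature_is_daily_aggregate(self, small_net):
        region = "R1"
        stations = small_net.stations[region]
        comp = np.mean([s.frame["tmean"].to_numpy() for s in stations], axis=0)
        dates = stations[0].frame.index
        monthly = small_net.monthly[region]["temperature"].values
        for (year, month) in [(1950, 1), (1980, 10), (2018, 12)]:
            mask = (dates.year == year) & (dates.month == month)
            assert monthly[(year, month)] == pytest.approx(comp[mask].mean(),
                                                           abs=1e-12)

    def test_truth_table_one_row_per_event(self, small_net):
        assert len(small_net.truth) == len(small_net.params.events)

    def test_frost_severity_monotone_in_criteria_met(self):
        """Raising the reduction fraction never decreases the number of
        criteria met at the affected site-year."""
        from frostrings.detection import reconstruct_events
        counts = []
        for reduction in (0.25, 0.55):
            ev = InjectedEvent(type="frost", year=1990, region="R1",
                               sites=["R1s01", "R1s02"], reduction=reduction,
                               cold_snap_sd=2.5, warm_spell_days=8)
            p = demo_params(seed=17, n_regions=2, sites_per_region=4,
                            trees_per_site=8, with_events=False)
            p.events = [ev]
            net = simulate_network(p)
            res = reconstruct_events(net.targets, net.controls, net.stations,
                                     net.monthly, net.make_config())
            row = res.criteria.loc[("R1s01", 1990)]
            counts.append(sum(bool(row[c]) is True
                              for c in ("C1", "C2", "C3", "C4", "C5", "A1", "A2")
                              if not pd.isna(row[c])))
        assert counts[1] >= counts[0]
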