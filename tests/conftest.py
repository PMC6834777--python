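import numpy as np
import pandas as pd
import pytest

from frostrings.data_io import StationDaily
from frostrings.detection import reconstruct_events
from frostrings.synthetic import demo_params, simulate_network


def make_station(frame_or_years, station_id="st", tmin=None, tmean=None):
    """StationDaily from either a prepared frame or (years, tmin, tmean)."""
    if isinstance(frame_or_years, pd.DataFrame):
        return StationDaily(station_id=station_id, frame=frame_or_years)
    dates = frame_or_years
    return StationDaily(
        station_id=station_id,
        frame=pd.DataFrame({"tmin": tmin, "tmean": tmean}, index=dates),
    )


def constant_station(years, tmin=0.0, tmean=5.0, station_id="st"):
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    return make_station(dates, station_id,
                        np.full(len(dates), float(tmin)),
                        np.full(len(dates), float(tmean)))


@pytest.fixture(scope="session")
def small_net():
    """Two-region demonstration network with the standard injected events,
    at reduced site/tree counts so the whole suite can share one build."""
    return simulate_network(demo_params(seed=1, n_regions=2, sites_per_region=4,
                                        trees_per_site=8))


@pytest.fixture(scope="session")
def small_result(small_net):
    cfg = small_net.make_config()
    return reconstruct_events(small_net.targets, small_net.controls,
                              small_net.stations, small_net.monthly, cfg)
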