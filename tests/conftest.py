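import numpy as np
import pandas as pd
import pytest

from homerange import SimSpec, make_fixture_suite, read_tracks, simulate_track
from homerange.tracks import group_tracks


@pytest.fixture(scope="session")
def ou_track():
    """A range-resident (OU) track at fisher-like scale: ~0.6 km² variance, hourly-ish."""
    return simulate_track(
        SimSpec(model="ou", sigma2=1e6, tau_pos=3600.0, dt=600.0, n=250, seed=5)
    )


@pytest.fixture(scope="session")
def iid_track():
    return simulate_track(SimSpec(model="iid", sigma2=1e6, dt=600.0, n=500, seed=9))


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """Synthetic 6-animal population written to disk (2 weeks of hourly fixes)."""
    out = tmp_path_factory.mktemp("suite")
    manifest = make_fixture_suite(out, weeks=2, seed=7)
    return out, manifest


@pytest.fixture(scope="session")
def population(fixture_suite):
    out, _ = fixture_suite
    table = read_tracks(out / "population_generic.csv", crs=5070)
    return table


@pytest.fixture(scope="session")
def population_groups(population):
    return group_tracks(population, by=["id"], crs=5070)


def make_simple_track(x, y, start="2011-01-01", freq="1h", crs=5070, **kw):
    """Helper: track from raw coordinates with evenly spaced hourly times."""
    from homerange import Track

    x = np.asarray(x, dtype=float)
    t = pd.date_range(start, periods=len(x), freq=freq, tz="UTC")
    return Track(x=x, y=np.asarray(y, dtype=float), t=t, crs=crs, **kw)
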