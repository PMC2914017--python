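import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

import pelagos as pg


@pytest.fixture(scope="session")
def default_scheme():
    return pg.build_scheme()


@pytest.fixture(scope="session")
def fine_scheme():
    return pg.build_scheme(pg.FINE_BREAKPOINTS)


@pytest.fixture(scope="session")
def global_bathy():
    """A 1-degree global synthetic grid with the default hypsometry targets."""
    return pg.generate_bathymetry(180, 360, seed=1)


@pytest.fixture(scope="session")
def small_bathy():
    """A coarse global grid, cheap enough for replicate loops."""
    return pg.generate_bathymetry(36, 72, seed=0)


def make_flat_grid(depth, n_lat=18, n_lon=36):
    """Global grid of constant sea-floor depth."""
    return pg.BathymetryGrid.global_grid(n_lat, n_lon, np.full((n_lat, n_lon), float(depth)))


@pytest.fixture
def flat_grid():
    return make_flat_grid


def make_records(sample, bottom, lat=0.0, lon=0.0):
    """Record table from parallel sample/bottom depth sequences."""
    sample = np.atleast_1d(np.asarray(sample, dtype=float))
    bottom = np.atleast_1d(np.asarray(bottom, dtype=float))
    n = max(sample.size, bottom.size)
    return pd.DataFrame(
        {
            "latitude": np.broadcast_to(np.asarray(lat, float), n).copy(),
            "longitude": np.broadcast_to(np.asarray(lon, float), n).copy(),
            "sample_depth": np.broadcast_to(sample, n).copy(),
            "bottom_depth": np.broadcast_to(bottom, n).copy(),
        }
    )
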