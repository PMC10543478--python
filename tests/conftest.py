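import numpy as np
import pytest

from gridpop.core import Geometry, GridParams, RateMap
from gridpop.correlograms import autocorrelation_2d, population_autocorrelation
from gridpop.synthetic import ideal_rate_map, make_module, slice_to_track


@pytest.fixture(scope="session")
def arena():
    return Geometry(kind="arena", outer_radius=75.0)


@pytest.fixture(scope="session")
def track():
    return Geometry(kind="track", outer_radius=75.0, inner_radius=60.0)


@pytest.fixture(scope="session")
def disc(arena):
    return arena.mask()


@pytest.fixture(scope="session")
def module_params():
    """The reference module: 20 comodular cells, 45-cm spacing, 14.9 deg."""
    return make_module(20, spacing_mean=45.0, orient_mean=14.9, seed=1)


@pytest.fixture(scope="session")
def arena_maps(module_params, arena):
    return [ideal_rate_map(p, arena) for p in module_params]


@pytest.fixture(scope="session")
def track_maps(arena_maps, track):
    return [slice_to_track(m, track) for m in arena_maps]


@pytest.fixture(scope="session")
def arena_population(arena_maps, disc):
    corrs = [autocorrelation_2d(m, support_mask=disc) for m in arena_maps]
    return population_autocorrelation(corrs)


@pytest.fixture(scope="session")
def track_population(track_maps, disc):
    corrs = [autocorrelation_2d(m, support_mask=disc) for m in track_maps]
    return population_autocorrelation(corrs)


def gaussian_bump_map(centers, geometry, amplitude=8.0, width=4.0):
    """Compact-field test map: truncated Gaussian bumps, zero background."""
    X, Y = geometry.bin_centers()
    v = np.zeros_like(X)
    for cx, cy in centers:
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        bump = amplitude * np.exp(-r2 / (2 * width ** 2))
        bump[r2 > (3 * width) ** 2] = 0.0
        v = np.maximum(v, bump)
    mask = geometry.mask()
    return RateMap(values=np.where(mask, v, 0.0), visited_mask=mask,
                   origin=geometry.grid_origin, bin_size=geometry.bin_size)


@pytest.fixture(scope="session")
def small_arena():
    return Geometry(kind="arena", outer_radius=20.0)
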