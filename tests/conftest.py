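import numpy as np
import pytest

from ecocorridor import AntParams, GridRaster, make_regime_scenario, run_colony, search_region
from ecocorridor.mcr import cost_distance, least_cost_path


def grid(values, cell_size=30.0, origin=(0.0, 0.0), crs="EPSG:32648", nodata=None):
    return GridRaster(np.asarray(values, dtype=float), cell_size, origin, crs, nodata)


@pytest.fixture
def small_grid():
    return grid(np.arange(9.0).reshape(3, 3))


@pytest.fixture(scope="session")
def colony_runs():
    """One seeded colony run per local-resistance regime, shared across tests."""
    cache = {}

    def run(kind, shape=(60, 100), seed=7, scen_seed=3):
        key = (kind, shape, seed, scen_seed)
        if key not in cache:
            sc = make_regime_scenario(kind, shape=shape, seed=scen_seed)
            skel = least_cost_path(cost_distance(sc.resistance, [sc.start]), sc.end)
            region = search_region(skel, sc.resistance, 1500.0)
            params = AntParams(seed=seed)
            field = run_colony(sc.resistance, region, sc.start, sc.end, params)
            cache[key] = (sc, field, params)
        return cache[key]

    return run
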