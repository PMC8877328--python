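import numpy as np
import pytest

import spraydry as sd
from spraydry.wall_surrogate import build_training_set, fit_full


@pytest.fixture(scope="session")
def geom():
    return sd.DryerGeometry()


@pytest.fixture(scope="session")
def table1():
    return sd.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return sd.load_fixture("table2")


@pytest.fixture(scope="session")
def all_records(table1, table2):
    return table1.records + table2.records


@pytest.fixture(scope="session")
def labeled_records(all_records, geom):
    labeled, flagged = build_training_set(all_records, geom)
    assert not flagged
    return labeled


@pytest.fixture(scope="session")
def fixture_surrogate(labeled_records):
    """Deployment surrogate trained on every labeled fixture record."""
    return fit_full(labeled_records, seed=0)


@pytest.fixture(scope="session")
def small_grid(fixture_surrogate, geom):
    region = sd.fixture_region()
    grid = sd.mesh_region(region, n_target=1000)
    return sd.assign_tout(grid, fixture_surrogate, geom=geom)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
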