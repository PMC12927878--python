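import numpy as np
import pytest

from lotic import synthetic
from lotic.transect import Site, build_transect


@pytest.fixture
def toy_transect():
    """Three equidistant sites, constant velocity 5 km/h -> tt_cum (0, 2, 4)."""
    sites = [
        Site("A", 100.0, velocity=5.0, tcc=1e9, bsp=0.5, mean_cell_volume=0.1),
        Site("B", 90.0, velocity=5.0, tcc=2e9, bsp=0.4, mean_cell_volume=0.08),
        Site("C", 80.0, velocity=5.0, tcc=3e9, bsp=0.3, mean_cell_volume=0.06),
    ]
    return build_transect(sites, [10.0, 10.0])


@pytest.fixture(scope="session")
def jds3_truth():
    return synthetic.jds3like(seed=1)


@pytest.fixture(scope="session")
def jds3_transect(jds3_truth):
    return synthetic.generate_transect(jds3_truth)


@pytest.fixture(scope="session")
def jds3_table(jds3_truth, jds3_transect):
    return synthetic.generate_asv_table(jds3_truth, jds3_transect)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
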