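"""Shared small fixtures: everything is generated programmatically."""

import numpy as np
import pytest

from carloops import genome_model as gm
from carloops import residency as rs
from carloops import contacts as ct


@pytest.fixture(scope="session")
def small_map():
    """25 CARs on a 250 kb chromosome with a centromere."""
    m = gm.build_car_map(25, 250_000, centromere=125_000, seed=11)
    return m.with_high_residency(gm.classify_high_residency(m, 0.10))


@pytest.fixture(scope="session")
def regular_map():
    """26 CARs exactly 8 kb apart, occupancy 1 (deterministic loop array)."""
    pos = 10_000 + 8_000 * np.arange(26)
    return gm.CARMap("chrS", 230_000, pos, np.ones(26))


@pytest.fixture(scope="session")
def rendered_regular(regular_map):
    """Noise-free rendered map of the deterministic loop array."""
    pop = rs.simulate_population(regular_map, 10, seed=1)
    params = ct.RenderParams(total_reads=5_000_000, noise=False)
    return ct.render_map(pop, regular_map, params, bin_size=200)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
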