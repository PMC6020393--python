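import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from popaccess import NearestSet, RegionConfig, generate_region

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: A compact region config used by tests that do not study the urban-rural
#: gradient: 6 counties (one per NCHS class), small grid, fast pipeline.
SMALL = dict(
    grid_nx=12,
    grid_ny=10,
    spacing_mi=0.5,
    n_blocks=90,
    n_outlets=24,
    n_counties=6,
    county_rows=1,
    n_states=2,
)


def make_set(distances, origin="B1", metric="euclidean", ids=None):
    ids = ids or [f"O{j}" for j in range(len(distances))]
    pairs = sorted(zip(ids, map(float, distances)), key=lambda t: (t[1], t[0]))
    return NearestSet(origin, metric, pairs)


def random_set(rng, m=None, metric="euclidean", scale=10.0):
    m = m or int(rng.integers(1, 8))
    return make_set(rng.random(m) * scale + 1e-3, metric=metric)


@pytest.fixture(scope="session")
def small_region():
    return generate_region(RegionConfig(seed=11, **SMALL))


@pytest.fixture(scope="session")
def default_region():
    return generate_region(RegionConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def path_network():
    """A--B--C path with 1-mile edges at 30 mph (2 min each)."""
    from popaccess import build_network

    nodes = pd.DataFrame(
        {"node_id": ["A", "B", "C"], "lon": [0.0, 1.0, 2.0], "lat": [0.0, 0.0, 0.0]}
    )
    edges = pd.DataFrame(
        {"from": ["A", "B"], "to": ["B", "C"], "length_mi": [1.0, 1.0], "speed_mph": [30.0, 30.0]}
    )
    return build_network(nodes, edges, mode="planar")
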