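"""Shared fixtures.

The full-scale universe (400 families, the package default) is expensive to
build and reduce, so it is a session fixture shared by the directional
acceptance experiments; its non-redundant pools and pairwise-identity cache
are shared through a single PoolCache.  Unit tests use a small universe.
"""

from __future__ import annotations

import numpy as np
import pytest

from ssp_homlab import UniverseConfig, generate_universe
from ssp_homlab.experiments import PredictorSettings
from ssp_homlab.layouts import PoolCache

#: Master seed of the study universe; every acceptance experiment derives
#: its per-repeat seeds from its own layout seed, not from this.
UNIVERSE_SEED = 2015


@pytest.fixture(scope="session")
def universe():
    config = UniverseConfig(seed=UNIVERSE_SEED)
    return generate_universe(config)


@pytest.fixture(scope="session")
def pools(universe):
    cache = PoolCache(universe, default_target=1800)
    # The 0.9 pool serves most designs; build it once up front.
    cache.pool(0.9)
    return cache


@pytest.fixture(scope="session")
def settings():
    return PredictorSettings()


@pytest.fixture(scope="session")
def mini_universe():
    config = UniverseConfig(n_families=60, length_range=(120, 140), seed=7)
    return generate_universe(config)


@pytest.fixture(scope="session")
def mini_pools(mini_universe):
    return PoolCache(mini_universe)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
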