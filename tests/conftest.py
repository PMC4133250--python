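import numpy as np
import pytest

from retmap import (
    SimulationConfig,
    SpatialGrid,
    build_colliculus,
    build_retina,
    build_profiles,
)


@pytest.fixture(scope="session")
def retina():
    return build_retina(1200, seed=7)


@pytest.fixture(scope="session")
def colliculus():
    return build_colliculus(800, seed=7)


@pytest.fixture(scope="session")
def grid(colliculus):
    return SpatialGrid(colliculus)


@pytest.fixture(scope="session")
def profiles(retina, colliculus):
    return build_profiles(retina, colliculus)


def micro_config(**kw) -> SimulationConfig:
    """A deliberately small but dynamically complete configuration used for
    the scenario property tests: ~100 RGCs onto ~400 collicular cells with
    shortened phases.  Problem sizes are chosen so a full developmental run
    completes in well under a minute while preserving every mechanism."""
    base = dict(n_rgc=100, n_sc=400, phase1_h=1.0, phase2_h=2.0, seed=1,
                snapshot_min=0)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
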