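import numpy as np
import pytest

from nucsense import (
    ExchangeGeometry,
    Grid1D,
    PauseDistribution,
    PhaseRules,
    TurningDistribution,
    load_config,
)


@pytest.fixture(scope="session")
def model():
    """Packaged default configuration (literature parameter values)."""
    return load_config()


@pytest.fixture(scope="session")
def geometry(model):
    return model.geometry


@pytest.fixture(scope="session")
def transport(model):
    return model.transport


@pytest.fixture(scope="session")
def motion(model):
    return model.motion


@pytest.fixture(scope="session")
def groups(model):
    return model.groups


@pytest.fixture(scope="session")
def exch(geometry):
    return ExchangeGeometry.from_geometry(geometry)


@pytest.fixture(scope="session")
def grid():
    return Grid1D.make()


@pytest.fixture(scope="session")
def coarse_grid():
    return Grid1D.make(125)


@pytest.fixture(scope="session")
def rules():
    return PhaseRules(
        turning=TurningDistribution("uniform", low=0.3, high=0.9),
        pause=PauseDistribution("exponential", mean=1.0),
        dt=1e-3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
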