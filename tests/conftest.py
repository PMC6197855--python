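import numpy as np
import pytest

from kinfret import presets
from kinfret.kinetic_models import ExperimentCondition, KineticScheme, Rate


@pytest.fixture(scope="session")
def two_state_scheme():
    """Fast-cycling two-state chain (first-order on-rate) for dwell stats."""
    return KineticScheme(
        ["U", "P"],
        [0.0, 0.4],
        {("U", "P"): Rate(2.0), ("P", "U"): Rate(0.28)},
    )


@pytest.fixture(scope="session")
def contact_scheme():
    return presets.contact_only_scheme()


@pytest.fixture(scope="session")
def wt_scheme():
    return presets.two_step_scheme()


@pytest.fixture(scope="session")
def branched_scheme():
    return presets.branched_scheme()


@pytest.fixture(scope="session")
def condition():
    return presets.default_condition()


@pytest.fixture(scope="session")
def short_condition():
    """300 frames (30 s) for cheap rendering tests."""
    return ExperimentCondition(30e-9, 0.1, 300)


@pytest.fixture(scope="session")
def noiseless_emission():
    return presets.default_emission(noise_sd=0.0, bleedthrough_fraction=0.0,
                                    donor_bleach_rate=0.0, acceptor_bleach_rate=0.0)


@pytest.fixture(scope="session")
def emission():
    return presets.default_emission()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
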