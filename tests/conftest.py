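import numpy as np
import pytest
from hypothesis import settings

from etongue.design import DesignSpec, LevelTable, build_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from etongue.ions import SolutionSample
from etongue.sensors import default_array_config


@pytest.fixture(scope="session")
def quiet_array():
    """Noise-free, drift-free array: deterministic forward model."""
    return default_array_config(drift_sd=0.0, noise_sd=0.0,
                                ec_noise_sd=0.0, ph_noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_array():
    """The default study array (drift 5 mV, electrode noise 0.5 mV)."""
    return default_array_config()


@pytest.fixture
def mixed_sample():
    return SolutionSample({"NO3": 300, "NH4": 20, "K": 100, "Ca": 60,
                           "Na": 40, "Cl": 80, "H2PO4": 100, "Mg": 30}, 22.0)


@pytest.fixture(scope="session")
def small_dataset():
    """27-run (3-level) dataset on the default array; fast to model."""
    spec = DesignSpec(n_levels=3, seed=11)
    samples, records = build_dataset(spec, LevelTable(),
                                     default_array_config(session_seed=11))
    return samples, records


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
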