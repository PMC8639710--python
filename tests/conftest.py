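import numpy as np
import pytest

from aslscov import AcquisitionParams, CohortConfig, build_phantom


@pytest.fixture(scope="session")
def default_params() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def noiseless_params() -> AcquisitionParams:
    return AcquisitionParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A 16^3 grid config for fast tests."""
    return CohortConfig(grid=(16, 16, 16), voxel_size_mm=(6.0, 6.0, 6.0))


@pytest.fixture(scope="session")
def control_phantom(small_config):
    return build_phantom(small_config, "control", (70.0, "f", "site_a"), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
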