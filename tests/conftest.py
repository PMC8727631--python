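import numpy as np
import pytest

from sescope.simulate import SimulationConfig, make_truth


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return make_truth(default_config)


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory, default_config):
    """One shared synthetic input bundle on disk (expensive to rebuild)."""
    from sescope.pipeline import simulate_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(default_config, outdir)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
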