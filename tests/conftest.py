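import numpy as np
import pytest

from ccdnet.filters import FilterConfig, filter_trace
from ccdnet.pipeline import stratified_split
from ccdnet.segment import SegmentationConfig
from ccdnet.simulate import SimulatorConfig, make_dataset, simulate_trace


@pytest.fixture(scope="session")
def sim_config():
    return SimulatorConfig(seed=11)


@pytest.fixture(scope="session")
def trace60(sim_config):
    """One minute of default-condition simulated accelerometry."""
    return simulate_trace(sim_config, 60.0)


@pytest.fixture(scope="session")
def filtered60(trace60):
    return filter_trace(trace60, FilterConfig())


@pytest.fixture(scope="session")
def scfg72():
    return SegmentationConfig(effective_points=72)


@pytest.fixture(scope="session")
def separable_dataset(scfg72):
    """400 boundary-margin pulses, balanced classes, via the full path."""
    return make_dataset(
        400, 0.5, SimulatorConfig.separable(seed=5), segmentation_config=scfg72
    )


@pytest.fixture(scope="session")
def separable_splits(separable_dataset):
    return stratified_split(separable_dataset, 280, 60, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
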