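import numpy as np
import pytest

from edsimopt import ResourceConfig, ServiceModel, WorkloadModel


@pytest.fixture
def workload():
    return WorkloadModel()


@pytest.fixture
def service():
    return ServiceModel()


@pytest.fixture
def current_config():
    return ResourceConfig(1, 2, 3, 1, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
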