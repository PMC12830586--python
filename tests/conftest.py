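import numpy as np
import pytest

from clocksync import ResettingExperiment, default_model


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def experiment(model):
    """Converged limit cycle + cached unperturbed reference run."""
    return ResettingExperiment(model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
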