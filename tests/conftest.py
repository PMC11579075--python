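import logging

import pytest

from hpaxis import Scenario, StructuralParams, VarianceComponents, simulate_individual

# the Base-EC50 projection warning is expected with the default components
logging.getLogger("hpaxis.population").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def theta():
    return StructuralParams()


@pytest.fixture(scope="session")
def omega():
    return VarianceComponents()


@pytest.fixture(scope="session")
def omega_zero():
    return VarianceComponents(**{k: 0.0 for k in VarianceComponents().to_dict()})


@pytest.fixture(scope="session")
def healthy_sim(theta):
    """Typical 70 kg healthy subject, 72 h warm-up, one output day."""
    return simulate_individual(theta, Scenario())


@pytest.fixture(scope="session")
def severity_sims(theta):
    """Typical trajectories across remaining enzymatic activities."""
    acts = (1.0, 0.5, 0.2, 0.05, 0.0)
    return {a: simulate_individual(theta, Scenario(activity=a)) for a in acts}
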