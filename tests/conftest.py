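import numpy as np
import pytest

from ingarch_dpd import (GEOMETRIC, POISSON, DPDConfig, ModelSpec, negbin,
                         simulate_ingarch)

FAST_CONFIG = DPDConfig(n_multistart=1)


@pytest.fixture(scope="session")
def poisson_model():
    return ModelSpec(POISSON)


@pytest.fixture(scope="session")
def nb_model():
    return ModelSpec(negbin(10))


@pytest.fixture(scope="session")
def geom_model():
    return ModelSpec(GEOMETRIC)


@pytest.fixture(scope="session")
def models(poisson_model, nb_model, geom_model):
    return {"poisson": poisson_model, "negbin": nb_model,
            "geometric": geom_model}


@pytest.fixture(scope="session")
def poisson_series(poisson_model):
    """A clean Poisson INGARCH(1,1) draw used across tests."""
    y, _ = simulate_ingarch(poisson_model, (1.0, 0.2, 0.2), 1000, seed=7)
    return y


@pytest.fixture(scope="session")
def fast_config():
    return FAST_CONFIG
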