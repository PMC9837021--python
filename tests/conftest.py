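import numpy as np
import pytest

from fibermech.composition import load_fibers, load_phases


@pytest.fixture(scope="session")
def props():
    return load_phases()


@pytest.fixture(scope="session")
def db():
    return load_fibers()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230112)


@pytest.fixture(scope="session")
def predictions():
    """Full 26-fiber x 3-scenario prediction table, computed once."""
    from fibermech.pipeline import predict_all

    return predict_all()
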