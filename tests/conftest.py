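import numpy as np
import pytest

from ednarisk import SyntheticSpec, generate_community, generate_samples, load_fixture
from ednarisk.teq import teq_series, teq_vector


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table5():
    return load_fixture("table5")


@pytest.fixture(scope="session")
def table7():
    return load_fixture("table7")


@pytest.fixture(scope="session")
def table9():
    return load_fixture("table9")


@pytest.fixture(scope="session")
def spec42():
    return SyntheticSpec(seed=42)


@pytest.fixture(scope="session")
def samples42(spec42):
    return generate_samples(spec42)


@pytest.fixture(scope="session")
def community42(spec42, samples42):
    return generate_community(spec42, samples42)


@pytest.fixture(scope="session")
def teq42(samples42):
    return teq_vector(teq_series(samples42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
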