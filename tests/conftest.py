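import numpy as np
import pytest

from plectopin import load_param_set, null_param_set


@pytest.fixture(scope="session")
def default_params():
    return load_param_set("default")


@pytest.fixture(scope="session")
def null_params():
    return null_param_set()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180907)


def random_dna(n, seed):
    r = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[r.integers(0, 4, n)])


@pytest.fixture(scope="session")
def random_20kb():
    return random_dna(20_000, 7)
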