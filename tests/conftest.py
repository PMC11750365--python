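import numpy as np
import pytest

from herbcomp import DEFAULT_TRUTH, DesignSpec, NoiseModel, gen_assay_table


@pytest.fixture(scope="session")
def truth():
    return DEFAULT_TRUTH


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def noiseless_table(truth, design):
    return gen_assay_table(truth, design, NoiseModel.noiseless())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
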