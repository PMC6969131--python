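import numpy as np
import pytest

from nvcouple.montage import default_montage
from nvcouple.paradigm import build_paradigm
from nvcouple.probe import build_probe
from nvcouple.synthetic import SubjectParams


@pytest.fixture(scope="session")
def layout():
    return build_probe()


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def schedule_1():
    return build_paradigm(1, seed=0)


@pytest.fixture(scope="session")
def schedule_2():
    return build_paradigm(2, seed=0)


@pytest.fixture()
def noiseless_params():
    return SubjectParams(group="healthy").noiseless()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
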