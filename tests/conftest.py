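import numpy as np
import pytest

import rivddi as rd
from rivddi import constants as C


@pytest.fixture(scope="session")
def human_control() -> rd.ModelParameters:
    return rd.extrapolate_to_human(C.RAT_TYPICAL_PER_KG, C.RAT, C.HUMAN, C.HUMAN_KA)


@pytest.fixture(scope="session")
def human_test(human_control) -> rd.ModelParameters:
    test = rd.apply_cbz(human_control, C.CBZ_EFFECTS)
    return test.replace(d2=C.D2_TEST_TABLE)


@pytest.fixture(scope="session")
def variability() -> rd.VariabilityModel:
    return rd.VariabilityModel(**C.VARIABILITY_DEFAULTS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230502)


def random_valid_params(rng: np.random.Generator) -> rd.ModelParameters:
    """A random parameter set spanning realistic small/large-animal ranges."""

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return rd.ModelParameters(
        cl_f=logu(0.1, 20.0),
        vc_f=logu(1.0, 100.0),
        q_f=logu(0.1, 20.0),
        vp_f=logu(10.0, 500.0),
        ka=logu(0.3, 5.0),
        d2=logu(1.0, 10.0),
        f1=float(rng.uniform(0.05, 0.95)),
        alag2=float(rng.uniform(0.0, 1.0)),
    )
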