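import numpy as np
import pytest

from biospike.sensor import LobeKinetics, SensorModel, default_sensor
from biospike.cell import CellParams, default_cell


@pytest.fixture(scope="session")
def toy_sensor():
    """Small two-lobe sensor with a fast N lobe and slow C lobe."""
    return SensorModel(
        lobe_N=LobeKinetics(k_off_ca=500.0, K_a=0.3, H=1.2,
                            k_on_pep=2000.0, k_off_pep=60.0),
        lobe_C=LobeKinetics(k_off_ca=20.0, K_a=1.5, H=1.5,
                            k_on_pep=200.0, k_off_pep=5.0),
        R_f=20.0)


@pytest.fixture(scope="session")
def jgcamp8f():
    return default_sensor("jgcamp8f")


@pytest.fixture(scope="session")
def gcamp6f():
    return default_sensor("gcamp6f")


@pytest.fixture(scope="session")
def jgcamp7f():
    return default_sensor("jgcamp7f")


@pytest.fixture(scope="session")
def bouton():
    return default_cell()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
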