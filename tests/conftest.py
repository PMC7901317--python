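import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from brunox.chromophores import TissueParams, load_default_table, resample
from brunox.experiments import DEFAULT_GRID

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID.copy()


@pytest.fixture(scope="session")
def table_on_grid(table, grid):
    return resample(table, grid)


@pytest.fixture(scope="session")
def model1_params():
    """Grey-matter optical properties without water; true StO2 = 65.1%."""
    return TissueParams(c_hbo2=55.0, c_hhb=29.5, wf=0.0, a=0.5, b=1.7)
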