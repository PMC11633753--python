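import numpy as np
import pytest
from hypothesis import settings

from glomflow import orn_biophysics as ob

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cell():
    return ob.build_cell()


@pytest.fixture(scope="session")
def v_rest(cell):
    return ob.resting_potential(cell)


@pytest.fixture(scope="session")
def m_weak(cell, v_rest):
    return ob.calibrate_m(cell, "weak", v_rest=v_rest)


@pytest.fixture(scope="session")
def m_strong(cell, v_rest):
    return ob.calibrate_m(cell, "strong", v_rest=v_rest)
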