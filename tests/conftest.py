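import numpy as np
import pytest

from nanoheat import optics
from nanoheat.materials import gold, silica, water
from nanoheat.thermometry import ThermalEnvironment


@pytest.fixture(scope="session")
def au():
    return gold()


@pytest.fixture(scope="session")
def env():
    return ThermalEnvironment()


@pytest.fixture(scope="session")
def nanoshell():
    return optics.silica_gold_nanoshell()


@pytest.fixture(scope="session")
def sphere150():
    return optics.solid_gold_sphere(150.0)


@pytest.fixture(scope="session")
def sphere80():
    return optics.solid_gold_sphere(80.0)


@pytest.fixture(scope="session")
def nanoshell_spectrum(nanoshell):
    return optics.spectrum(nanoshell)


@pytest.fixture(scope="session")
def sphere150_spectrum(sphere150):
    return optics.spectrum(sphere150)


@pytest.fixture(scope="session")
def sphere80_spectrum(sphere80):
    return optics.spectrum(sphere80)
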