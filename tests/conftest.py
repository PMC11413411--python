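import numpy as np
import pytest

from wolbkrig import load_survey_table
from wolbkrig.geodesy import SiteSet
from wolbkrig.variogram import VariogramModel


@pytest.fixture(scope="session")
def survey():
    """The packaged 2018-2022 field survey (15 populations)."""
    return load_survey_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240920)


@pytest.fixture(scope="session")
def small_sites():
    """Ten fixed sites over central Europe for solver-level tests."""
    g = np.random.default_rng(7)
    lats = g.uniform(44.0, 54.0, 10)
    lons = g.uniform(2.0, 20.0, 10)
    return SiteSet.from_array(np.column_stack([lats, lons]))


@pytest.fixture(scope="session")
def truth_model():
    return VariogramModel(C0=0.05, C1=0.20, b=600.0)
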