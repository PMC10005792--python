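import numpy as np
import pytest

import nmrdfit as nf


@pytest.fixture(scope="session")
def catalog():
    return nf.load_default_catalog()


@pytest.fixture(scope="session")
def grid32():
    return nf.FrequencyGrid.log_spaced(1e4, 1e7, 32)


@pytest.fixture(scope="session")
def bear298(catalog):
    return catalog.model_for("bear", 298)


@pytest.fixture(scope="session")
def bear323(catalog):
    return catalog.model_for("bear", 323)


def make_seeded_profile(model, grid, cv, seed, **kw):
    return nf.make_profile(model, grid, nf.NoiseSpec(cv, seed), **kw)


@pytest.fixture
def seeded_profile():
    return make_seeded_profile
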