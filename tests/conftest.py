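import pytest

from sprucestand import (
    AllometryParams,
    PFTParams,
    ProductivityParams,
    build_mass_grid,
)


@pytest.fixture(scope="session")
def allom():
    return AllometryParams()


@pytest.fixture(scope="session")
def pft():
    return PFTParams()


@pytest.fixture(scope="session")
def prod():
    return ProductivityParams()


@pytest.fixture(scope="session")
def grid(allom, pft):
    return build_mass_grid(K=10, m_seed=1.0, ratio=2.0, allom=allom, pft=pft)
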