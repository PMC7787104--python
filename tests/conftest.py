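import numpy as np
import pytest

from refltriage import symmetry as sym
from refltriage.reflection_data import ReflectionDataset, UnitCell
from refltriage.simulate import unique_reflections


@pytest.fixture
def cubic_cell():
    return UnitCell(40.0, 40.0, 40.0)


@pytest.fixture
def p422_cell():
    return UnitCell(45.0, 45.0, 77.0)


def make_dataset(laue="2", cell=None, d_min=2.0, seed=0, scale=100.0):
    """Clean Wilson draws on a full canonical index set."""
    cell = cell or UnitCell(30.0, 35.0, 40.0)
    pg = sym.point_group(laue)
    hkl = unique_reflections(cell, pg, d_min)
    rng = np.random.default_rng(seed)
    eps = sym.epsilon_factors(hkl, pg).astype(float)
    centric = sym.centric_flags(hkl, pg)
    z = np.where(centric, rng.normal(size=len(hkl)) ** 2, rng.exponential(size=len(hkl)))
    I = scale * eps * z
    sigI = 0.02 * np.abs(I) + 0.5
    return ReflectionDataset(
        hkl=hkl, I=I, sigI=sigI, cell=cell, laue_symbol=laue,
        _skip_canonicalization=True,
    )


@pytest.fixture
def small_dataset():
    return make_dataset(seed=3)
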