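import numpy as np
import pytest

from ulktether.library import DihedralLibrary


@pytest.fixture(scope="session")
def library():
    return DihedralLibrary.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def helix_dihedrals(n):
    return [(-60.0, -45.0, 180.0)] * n


def random_dihedrals(n, rng):
    return np.column_stack([rng.uniform(-179.0, 180.0, n),
                            rng.uniform(-179.0, 180.0, n),
                            np.full(n, 180.0)])
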