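import numpy as np
import pytest

from gsuremri.forward_model import SenseOperator, make_mask
from gsuremri.synth import make_coil_maps, make_phantom


@pytest.fixture
def phantom16():
    return make_phantom((16, 16), 3, seed=0)


@pytest.fixture
def maps16():
    return make_coil_maps((16, 16), 4, seed=1, normalize=True)


@pytest.fixture
def full_op16(maps16):
    return SenseOperator(maps=maps16, mask=None)


@pytest.fixture
def masked_op16(maps16):
    mask = make_mask((16, 16), R=2, acs_width=4, seed=2)
    return SenseOperator(maps=maps16, mask=mask)


def random_complex(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
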