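import numpy as np
import pytest

from alpsflow import AcquisitionScheme, default_scheme


@pytest.fixture(scope="session")
def scheme32() -> AcquisitionScheme:
    """One b0 plus 32 uniform directions at b = 1000 s/mm^2."""
    return default_scheme(n_directions=32)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_spd_tensor(rng, scale=1e-3) -> np.ndarray:
    """A random symmetric positive-definite tensor on a diffusivity scale."""
    a = rng.normal(size=(3, 3))
    return scale * (a @ a.T / 3 + 0.2 * np.eye(3))
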