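import numpy as np
import pytest

from emdmn import PhantomParams, generate_field


@pytest.fixture(scope="session")
def small_phantom():
    """A compact noiseless phantom: 5 nuclei, 2 rich + 2 NE-level MN."""
    params = PhantomParams(
        field_size_px=(256, 256),
        n_nuclei=5,
        n_mn_rich=2,
        n_mn_ne=2,
        noise_sd=0.0,
        seed=7,
    )
    return params, generate_field(params)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-parameter phantom field (20 nuclei, 4 + 4 MN, noise)."""
    params = PhantomParams(seed=11)
    return params, generate_field(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
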