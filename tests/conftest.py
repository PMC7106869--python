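import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from echosketch import phantom as ph

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_params():
    return ph.PhantomParams(seed=1)


@pytest.fixture(scope="session")
def sample(default_params):
    """One fully rendered phantom pair, shared across tests."""
    return ph.generate_paired_sample(default_params)


@pytest.fixture(scope="session")
def small_dataset():
    """Twelve paired 64px phantoms for training smoke tests."""
    out = []
    for i in range(12):
        s = ph.generate_paired_sample(ph.PhantomParams(seed=500 + i))
        out.append((s.ultrasound, s.sketch))
    return out

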