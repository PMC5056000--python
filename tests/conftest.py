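import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def random_complex_image(rng):
    return rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))


@pytest.fixture
def small_phantom():
    from trims.phantoms import PhantomSpec, make_phantom

    return make_phantom(PhantomSpec(kind="shepp_logan", n=64, phase_model="smooth_random", seed=11))
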