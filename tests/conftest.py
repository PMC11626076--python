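import numpy as np
import pytest

from ctqa import CTImage, PhantomSpec


@pytest.fixture
def flat_image():
    """Constant soft-tissue image, 0.5 mm isotropic spacing."""
    return CTImage(pixels=np.full((64, 64), 40.0), spacing_x=0.5, spacing_y=0.5)


@pytest.fixture
def small_spec():
    """A reduced phantom spec for quick generator tests."""
    return PhantomSpec(size=256, seed=123)


@pytest.fixture
def default_spec():
    return PhantomSpec(seed=123)


@pytest.fixture(scope="session")
def noiseless_stack():
    """Full-size noiseless phantom stack, shared across tests (read-only)."""
    from ctqa import generate_phantom_stack

    spec = PhantomSpec(seed=0)
    stack, truth = generate_phantom_stack(spec, noise_sd=0.0)
    return spec, stack, truth
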