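import numpy as np
import pytest

from paraseg.phantoms import PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def noiseless_spec():
    """Phantom with zero HU variance everywhere: tissue means only."""
    return PhantomSpec(image_size=128, noise_sd=0, muscle_hu_sd=0,
                       fat_hu_sd=0, bone_hu_sd=0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec(image_size=128)
    return generate_phantom(spec), spec


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 patients x 4 slices at 32 px — enough for split/CV plumbing tests."""
    spec = PhantomSpec(image_size=32)
    return generate_cohort(8, 4, spec, seed=11)


def single_blob_mask(n=100, center=(50, 40), r=9):
    yy, xx = np.mgrid[:n, :n]
    return (((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= r * r).astype(np.uint8)
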