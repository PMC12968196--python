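import numpy as np
import pytest

from cedplan import PhantomSpec, Volume, generate_phantom


def make_volume(data, voxel=1.0, origin=(0.0, 0.0, 0.0)):
    aff = np.eye(4)
    aff[:3, :3] *= voxel
    aff[:3, 3] = origin
    return Volume(np.asarray(data), aff)


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free, jitter-free default phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
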