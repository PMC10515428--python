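import numpy as np
import pytest

from barriermap import AcquisitionTimes, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def times8() -> AcquisitionTimes:
    """Default 8-frame schedule within [1, 30] min post injection."""
    return AcquisitionTimes(np.array([1.0, 2.5, 5.0, 8.0, 12.0, 17.0, 23.0, 30.0]))


@pytest.fixture(scope="session")
def small_noiseless_phantom():
    """A 32^3 treated phantom without noise, shared across tests."""
    spec = PhantomSpec(
        shape=(32, 32, 32), n_clusters=2, n_sham_components=3,
        noise_sigma=0.0, seed=11,
    )
    return generate_phantom(spec)
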