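import numpy as np
import pytest

from spikect import PhantomSpec, generate_spike

#: coarse voxel size used by fast test phantoms (geometry unchanged)
COARSE_UM = 154.0


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 5-spikelet, 3-grain phantom at half resolution: fast but realistic."""
    return PhantomSpec(
        n_spikelets=5, grains_per_spikelet=3, voxel_size_um=COARSE_UM, seed=11
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_spike(small_spec)


@pytest.fixture(scope="session")
def noisy_touching_phantom():
    spec = PhantomSpec(
        n_spikelets=5,
        grains_per_spikelet=3,
        voxel_size_um=COARSE_UM,
        noise_sd=250.0,
        touching_fraction=0.3,
        seed=12,
    )
    return generate_spike(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
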