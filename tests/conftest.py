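import numpy as np
import pytest

from strainpet import PhantomParams, generate_phantom
from strainpet.aeration import AerationMap


def make_aeration(gas_fractions: np.ndarray, voxel_volume: float = 1.0, mask=None) -> AerationMap:
    """Build an AerationMap directly from gas fractions (test helper)."""
    gas_fractions = np.asarray(gas_fractions, dtype=float)
    if mask is None:
        mask = np.ones_like(gas_fractions, dtype=bool)
    gas = gas_fractions * voxel_volume
    return AerationMap(
        gas_volume=gas,
        nongaseous_volume=voxel_volume - gas,
        mask=np.asarray(mask, dtype=bool),
        voxel_volume=voxel_volume,
    )


@pytest.fixture(scope="session")
def small_params():
    """Small, quick-to-generate phantom parameters (noisy)."""
    return PhantomParams(grid_shape=(10, 64, 16), seed=11)


@pytest.fixture(scope="session")
def noisefree_params():
    """Noise-free phantom without atelectasis, inflation kept below the
    gas-fraction cap so strain is uniform."""
    return PhantomParams(
        grid_shape=(10, 64, 16),
        aeration_top=0.45,
        aeration_gradient=0.2,
        atelectasis_depth_fraction=0.0,
        inflation_factor=1.8,
        pet_noise_sd=0.0,
        ct_noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def noisefree_phantom(noisefree_params):
    return generate_phantom(noisefree_params)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return generate_phantom(small_params)
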