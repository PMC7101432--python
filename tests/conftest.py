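import numpy as np
import pytest

from petmodnet import PhantomSpec, make_tumor_phantom
from petmodnet.imaging import PETVolume, TumorMask


@pytest.fixture(scope="session")
def uniform_phantom():
    """Zero-noise, homogeneous-uptake sphere-like phantom (2 mm grid)."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        base_radius=30.0,
        noise_sd=0.0,
        lumpiness=(0, 0.0),
        boundary_perturbation=0.0,
    )
    return make_tumor_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_volume_mask(shape=(4, 4, 4), n_bins=4, seed=0, spacing=(1.0, 1.0, 1.0)):
    """Small random pre-discretized grid + full mask, for texture oracles."""
    rng = np.random.default_rng(seed)
    disc = rng.integers(1, n_bins + 1, size=shape).astype(np.int32)
    mask = TumorMask(np.ones(shape, dtype=bool), spacing)
    return disc, mask


@pytest.fixture
def tiny_suv_volume():
    """20^3 grid with a hot sphere (max 10) over background 1."""
    shape = (20, 20, 20)
    coords = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    d = np.linalg.norm(coords - 9.5, axis=-1)
    values = 1.0 + 9.0 * np.clip(1 - d / 6.0, 0, 1)
    return PETVolume(values, (1.0, 1.0, 1.0), calibrated=True)
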