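import numpy as np
import pytest

from emvolscore.contouring import ContourSpec
from emvolscore.synthetic import Blob, PhantomSpec, default_spec, make_phantom
from emvolscore.volume_io import DensityMap


def contour_at(threshold: float, sigma: float = 1.0, peak: float = 0.0) -> ContourSpec:
    """Hand-built contour spec for tests that fix the threshold directly."""
    return ContourSpec(
        threshold=threshold, method="author", background_peak=peak, sigma=sigma
    )


@pytest.fixture
def single_blob_map() -> DensityMap:
    """Noise-free isotropic blob centered on a 32^3 grid, 2 A spacing."""
    spec = PhantomSpec(
        blobs=(Blob((31.0, 31.0, 31.0), 36.0 * np.eye(3), 1.0),),
        grid_shape=(32, 32, 32),
        spacing=2.0,
        resolution=8.0,
        noise_sd=0.0,
        seed=0,
    )
    return make_phantom(spec)


@pytest.fixture
def multi_blob_map() -> DensityMap:
    """Seeded noisy multi-blob phantom, the standard test subject."""
    return make_phantom(default_spec(seed=5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
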