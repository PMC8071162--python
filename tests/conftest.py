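import numpy as np
import pytest

from hepaquant import BinaryMask, Image2D, PhantomSpec, generate_phantom
from hepaquant.pipeline import default_init_mask


@pytest.fixture(scope="session")
def default_phantom():
    """Default 256x256 phantom: CV 0.05, 20% bias, no nodularity, seed 2."""
    spec = PhantomSpec(parenchyma_cv=0.05, bias_amplitude=0.2, noise_seed=2)
    image, truth = generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def disk_scene():
    """128x128 two-phase disk (r = 40 px) with 5% relative noise."""
    rng = np.random.default_rng(0)
    rr, cc = np.mgrid[0:128, 0:128]
    mask = (rr - 64) ** 2 + (cc - 64) ** 2 <= 40**2
    base = np.where(mask, 100.0, 30.0)
    noisy = np.clip(base * (1 + 0.05 * rng.standard_normal(base.shape)), 0, None)
    return {
        "clean": Image2D(base, (1.0, 1.0)),
        "noisy": Image2D(noisy, (1.0, 1.0)),
        "mask": BinaryMask(mask),
        "init": default_init_mask((128, 128), (64.0, 64.0), 25.0),
    }
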