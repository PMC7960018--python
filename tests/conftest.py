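import numpy as np
import pytest

import sparsesvr as svr


@pytest.fixture(scope="session")
def phantom32():
    return svr.generate_phantom((32, 32, 32), spacing=1.0, seed=0)


@pytest.fixture(scope="session")
def smooth_volume():
    """Band-limited smooth scalar field on a 24^3 grid, range ~[0, 200]."""
    n = 24
    ax = np.linspace(-1, 1, n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    f = 100 + 60 * np.sin(1.5 * x + 0.3) * np.cos(1.2 * y) + 40 * np.cos(1.1 * z - 0.2)
    return f


@pytest.fixture(scope="session")
def still_dataset(phantom32):
    """Three orthogonal stacks, no motion/noise/bias, no removal."""
    cfg = svr.AcquisitionConfig(
        motion_amplitude=(0.0, 0.0),
        noise_sigma=0.0,
        bias_amplitude=0.0,
        scale_range=(1.0, 1.0),
        removal_proportion=0.0,
        seed=7,
    )
    stacks, gt = svr.simulate_dataset(cfg, gt=phantom32)
    return stacks, gt


def identity_slice(pixels, spacing=1.0, thickness=1.0, **kw):
    """Slice whose world affine is the identity (pixel index == world mm)."""
    return svr.Slice(
        pixels=np.asarray(pixels, dtype=float),
        spacing=spacing,
        thickness=thickness,
        world=np.eye(4),
        **kw,
    )
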