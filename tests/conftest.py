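import numpy as np
import pytest

import oxymap as ox


@pytest.fixture(scope="session")
def cal():
    """Synthetic 3-point calibration (1.0 G at anoxia, 0.01 G/torr)."""
    return ox.default_calibration()


@pytest.fixture(scope="session")
def small_scheme():
    """Scaled-down acquisition (16 x 8 angles) for fast round trips."""
    return ox.build_scheme(16, 8, 3.0, 4.24, 5.0, 256, 390.95)


@pytest.fixture(scope="session")
def uniform_disc():
    """32 x 32 disc phantom at uniform 20 torr."""
    return ox.make_uniform_phantom(32, po2=20.0)


@pytest.fixture(scope="session")
def small_projection_set(cal, small_scheme, uniform_disc):
    """Noiseless projections of the uniform disc under the small scheme."""
    return ox.forward_project(uniform_disc, cal, small_scheme)


def brute_force_hf(po2, mask, threshold=10.0):
    """Independent pixel-loop hypoxic fraction used as oracle."""
    n = 0
    k = 0
    for iy in range(po2.shape[0]):
        for ix in range(po2.shape[1]):
            if mask[iy, ix]:
                n += 1
                if po2[iy, ix] <= threshold:
                    k += 1
    return k / n


def random_oxygen_map(rng, size=12):
    """Random valid OxygenMap for statistics oracles."""
    po2 = rng.uniform(0, 60, size=(size, size))
    # sprinkle exact-boundary values to exercise the inclusive threshold
    nb = rng.integers(1, 5)
    iy = rng.integers(0, size, size=nb)
    ix = rng.integers(0, size, size=nb)
    po2[iy, ix] = 10.0
    amp = rng.uniform(0.5, 1.0, size=(size, size))
    mask = rng.random((size, size)) < 0.8
    mask.flat[0] = True  # never empty
    return ox.OxygenMap(po2=po2, amplitude=amp, valid_mask=mask,
                        pixel_size=0.03, clamp_flags=np.zeros_like(mask))
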