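"""Shared fixtures: small deterministic phantoms and geometries."""

import numpy as np
import pytest

import csetomo as cs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disc_slice():
    """A 64x64 two-density disc phantom supported in the inscribed circle."""
    n = 64
    xx, zz = np.meshgrid(np.arange(n) - (n - 1) / 2, np.arange(n) - (n - 1) / 2, indexing="ij")
    img = np.zeros((n, n))
    img[xx**2 + zz**2 < 18**2] = 0.7
    img[(xx - 6) ** 2 + (zz + 5) ** 2 < 7**2] = 1.0
    return img


@pytest.fixture(scope="session")
def tiny_membrane_volume():
    """A small membrane-phantom volume for volume-level plumbing tests."""
    spec = cs.MembranePhantomSpec(
        dims=(32, 6, 32),
        n_shells=3,
        n_filled=4,
        semiaxis_range=(2.0, 9.0),
        shell_thickness_range=(1.0, 2.0),
        seed=3,
    )
    return cs.make_membrane_phantom(spec)


@pytest.fixture(scope="session")
def coarse_angles():
    return cs.make_uniform_angles(70, 10)
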