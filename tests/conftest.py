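"""Shared fixtures: small deterministic phantoms and fields."""

from __future__ import annotations

import numpy as np
import pytest

from vesselseg.phantom import PhantomSpec, Tube, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def binary_cross_phantom():
    """Noise-free hard-profile phantom: two crossing tubes at 300 over 50."""
    spec = PhantomSpec(
        shape=(48, 48, 48), profile="hard", noise_sigma=0.0,
        tubes=[Tube((4, 24, 24), (44, 24, 24), 5.0, 300.0),
               Tube((24, 4, 20), (24, 44, 28), 4.0, 300.0)])
    return make_phantom(spec)


@pytest.fixture(scope="session")
def tube_phantom_r3():
    """Single straight radius-3 tube along axis 0 with noise sigma 10."""
    spec = PhantomSpec(
        shape=(48, 48, 48), profile="gaussian", noise_sigma=10.0, seed=4,
        tubes=[Tube((4, 24, 24), (44, 24, 24), 3.0, 300.0)])
    return make_phantom(spec)


@pytest.fixture(scope="session")
def smooth_random_volume(rng):
    """A smooth random 16^3 field for oracle comparisons."""
    from scipy import ndimage as ndi

    raw = rng.normal(0.0, 1.0, size=(16, 16, 16))
    return ndi.gaussian_filter(raw, 2.0, mode="nearest") * 50.0 + 100.0
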