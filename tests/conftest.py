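import numpy as np
import pytest

from nhdsim import (GaussianWellSpec, SquarePatchSpec, make_constant_profile,
                    make_gaussian_profile, make_patch_profile)


@pytest.fixture(scope="session")
def well_profile_1d():
    """The canonical 1D Gaussian viscosity well: D0=1, d=0.9, omega=0.1."""
    return make_gaussian_profile(GaussianWellSpec(D0=1.0, d=0.9, omega=0.1), L=1.0)


@pytest.fixture(scope="session")
def narrow_well_1d():
    return make_gaussian_profile(GaussianWellSpec(D0=1.0, d=0.9, omega=0.01), L=1.0)


@pytest.fixture(scope="session")
def flat_profile_1d():
    return make_constant_profile(1.0, L=1.0, dim=1)


@pytest.fixture(scope="session")
def patch_profile_2d():
    """Square slow patch, amplitude ratio 2, in a 24x24 box."""
    spec = SquarePatchSpec(patch_center=(-6.0, 6.0), patch_side=6.0,
                           ratio_r=2.0, edge_width=0.24)
    return make_patch_profile(spec, L=12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class StubRng:
    """Deterministic stand-in for a Generator: replays preset normal draws."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float).ravel()
        self.i = 0

    def standard_normal(self, shape):
        size = int(np.prod(shape))
        out = self.values[self.i:self.i + size]
        if out.size < size:
            raise RuntimeError("stub exhausted")
        self.i += size
        return out.reshape(shape)


@pytest.fixture
def stub_rng_factory():
    return StubRng
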