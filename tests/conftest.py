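import numpy as np
import pytest

from dmta import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def sinusoid_surface(amplitude=0.5, wavelength=10.0, n=200, dx=0.44,
                     stage="scale_limited", axis="x"):
    """A pure sinusoidal surface, the workhorse analytic fixture."""
    x = np.arange(n) * dx
    X, Y = np.meshgrid(x, x)
    G = X if axis == "x" else Y
    z = amplitude * np.sin(2 * np.pi * G / wavelength)
    return HeightMap(z, dx, dx, stage=stage)


@pytest.fixture
def sinusoid():
    return sinusoid_surface()
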