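import numpy as np
import pytest

from wemdalign.volumes import DensityMap


def anisotropic_gaussian(n=32, sigmas=(5.0, 4.0, 6.0), center=(0.0, 0.0, 0.0)):
    """Broad smooth anisotropic Gaussian blob, the stock band-limited test map."""
    idx = np.arange(n, dtype=float) - n // 2
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    cx, cy, cz = center
    sx, sy, sz = sigmas
    data = np.exp(
        -((x - cx) ** 2 / (2 * sx**2) + (y - cy) ** 2 / (2 * sy**2) + (z - cz) ** 2 / (2 * sz**2))
    )
    return DensityMap(data)


def isotropic_blob(n=32, sigma=3.0, center=(0.0, 0.0, 0.0)):
    return anisotropic_gaussian(n, (sigma, sigma, sigma), center)


@pytest.fixture(scope="session")
def smooth_map():
    """Compact smooth blob: tails < 1e-6 at the box edge, so the periodic
    Fourier operators behave like exact continuum ones."""
    return anisotropic_gaussian(32, sigmas=(2.8, 2.4, 2.6))


@pytest.fixture(scope="session")
def broad_map():
    """Broad blob for cross-backend comparisons (interpolation error shrinks
    with feature size; the fat tails wrap slightly, which both backends share)."""
    return anisotropic_gaussian(32, sigmas=(5.0, 4.0, 6.0))


@pytest.fixture(scope="session")
def four_lobe_16():
    from wemdalign.synthetic import default_spec, gaussian_mixture_map

    return gaussian_mixture_map(default_spec(16))


@pytest.fixture(scope="session")
def four_lobe_32():
    from wemdalign.synthetic import default_spec, gaussian_mixture_map

    return gaussian_mixture_map(default_spec(32))
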