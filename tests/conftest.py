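import numpy as np
import pytest

from fpiapw import (
    APWTemplate,
    OpticalConfig,
    roundtrip_validate,
    synthesize_recording,
)


@pytest.fixture(scope="session")
def optics():
    return OpticalConfig()


@pytest.fixture(scope="session")
def template():
    return APWTemplate()


@pytest.fixture(scope="session")
def clean_recording(template, optics):
    """Noise-free default recording shared across detection tests."""
    return synthesize_recording(template, optics, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_roundtrip(template, optics):
    """Full noise-free pipeline round trip (timing, snr, result, recording)."""
    return roundtrip_validate(template, optics, noise_sd=0.0, seed=1)


def dense_fringe_extrema_count(delta_z_nm, optics, oversample=50):
    """Brute-force oracle: count interference-intensity extrema on a dense grid.

    Evaluates the cosine interference law on an ``oversample``-times denser
    grid (linear interpolation of the displacement) and counts sign changes
    of the discrete derivative.  Independent of the package's peak
    detection machinery.
    """
    z = np.asarray(delta_z_nm, float)
    x = np.linspace(0, 1, z.size)
    xd = np.linspace(0, 1, z.size * oversample)
    zd = np.interp(xd, x, z)
    phase = (
        4.0 * np.pi * optics.refractive_index / optics.wavelength_nm
    ) * (optics.static_cavity_length_nm - zd) + np.pi
    intensity = (
        optics.intensity_fiber + optics.intensity_membrane
        + optics.fringe_amplitude * np.cos(phase)
    )
    d = np.diff(intensity)
    d = d[d != 0]
    return int(np.sum(np.sign(d[1:]) != np.sign(d[:-1])))
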