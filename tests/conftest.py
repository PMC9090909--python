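import numpy as np
import pytest

from photokin.spectra import (
    LampProfile,
    PhotoSpecies,
    ReactorGeometry,
    Spectrum,
    UNIT_DIMENSIONLESS,
    UNIT_EPSILON,
    UNIT_PHOTON_FLUX,
)
from photokin.synthetic import GaussianBand, SyntheticSystemSpec, make_system


@pytest.fixture(scope="session")
def geometry():
    return ReactorGeometry()


@pytest.fixture(scope="session")
def default_system():
    """The default dacarbazine-like synthetic system (broad mixed lamp)."""
    return make_system(SyntheticSystemSpec())


@pytest.fixture(scope="session")
def monochromatic_system():
    """High-absorbance system under an effectively single-wavelength lamp,
    where the lumped and per-wavelength rate laws coincide."""
    spec = SyntheticSystemSpec(
        bands_A=(GaussianBand(330.0, 30.0, 2.0e5),),
        bands_B=(GaussianBand(300.0, 25.0, 6.0e4),),
        qy_min=0.05,
        qy_max=0.4,
        lamp_lines=(GaussianBand(330.0, 0.15, 1.0),),
        C0=1.0e-4,
        name="mono-test",
        lamp_id="line-330",
    )
    return make_system(spec)


def toy_species(grid, eps_a, eps_b, qy):
    """Small hand-buildable species on an explicit grid."""
    grid = np.asarray(grid, dtype=float)
    return PhotoSpecies(
        Spectrum(grid, np.asarray(eps_a, float), UNIT_EPSILON),
        Spectrum(grid, np.asarray(eps_b, float), UNIT_EPSILON),
        Spectrum(grid, np.asarray(qy, float), UNIT_DIMENSIONLESS),
    )


def line_lamp(wavelength, flux, lamp_id="line"):
    """A lamp whose support is a single grid point."""
    return LampProfile(
        Spectrum([wavelength], [flux], UNIT_PHOTON_FLUX), lamp_id
    )
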