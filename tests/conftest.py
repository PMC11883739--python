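import numpy as np
import pytest

from nmrihm.components import ComponentModel, Feature, Multiplet
from nmrihm.lineshape import AcquisitionGrid


@pytest.fixture(scope="session")
def grid700():
    """High-resolution 700 MHz grid, 1 ppm window around 5 ppm."""
    return AcquisitionGrid(
        spectrometer_frequency=700.0,
        carrier_ppm=5.0,
        spectral_width=700.0,
        n_points=8192,
    )


@pytest.fixture(scope="session")
def grid500():
    """Routine 500 MHz grid, 10 ppm window around 5 ppm."""
    return AcquisitionGrid(
        spectrometer_frequency=500.0,
        carrier_ppm=5.0,
        spectral_width=5000.0,
        n_points=8192,
    )


@pytest.fixture(scope="session")
def grid500_small():
    return AcquisitionGrid(
        spectrometer_frequency=500.0,
        carrier_ppm=5.0,
        spectral_width=5000.0,
        n_points=4096,
    )


def singlet(center_ppm, fwhm=1.0, beta=0.0, label="s", amplitude=1.0):
    return Multiplet(
        center_ppm=center_ppm,
        features=(Feature(0.0, 1.0, fwhm, beta),),
        label=label,
        amplitude=amplitude,
    )


def doublet(center_ppm, J, fwhm=1.0, beta=0.0, label="d", amplitude=1.0):
    return Multiplet(
        center_ppm=center_ppm,
        features=(
            Feature(-J / 2, 0.5, fwhm, beta),
            Feature(J / 2, 0.5, fwhm, beta),
        ),
        label=label,
        amplitude=amplitude,
    )


def simple_component(name, mults, nuclei=1, amplitude=None):
    return ComponentModel(
        name=name,
        multiplets=tuple(mults),
        total_amplitude=float(nuclei if amplitude is None else amplitude),
        nuclei=nuclei,
    )


@pytest.fixture
def two_singlet_component(grid500):
    return simple_component(
        "pair", [singlet(7.0, label="a"), singlet(3.0, label="b")], nuclei=2
    )
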