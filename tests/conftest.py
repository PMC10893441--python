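import numpy as np
import pytest

from nirshift.simulate import (
    ComponentLibrary,
    InstrumentProfile,
    default_library,
    generate_paired,
    master_profile,
    slave_profile,
)
from nirshift.spectra import SpectraSet, WavelengthGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.linspace(900.0, 1700.0, 12))


@pytest.fixture
def small_set(small_grid, rng):
    X = rng.normal(1.0, 0.2, size=(8, len(small_grid)))
    y = rng.uniform(30.0, 120.0, size=8)
    return SpectraSet(small_grid, X, y, "unit-test")


@pytest.fixture(scope="session")
def tiny_paired():
    """A small paired master/slave dataset for smoke-level training tests."""
    lib = default_library()
    master = InstrumentProfile(n_channels=40, resolution_fwhm=2.0, noise_sd=0.002,
                               name="master")
    slave = InstrumentProfile(n_channels=24, resolution_fwhm=7.0, gain=1.25,
                              offset=0.08, baseline_slope=1.5e-4,
                              wavelength_shift=2.0, noise_sd=0.004, name="slave")
    return generate_paired(24, 30, lib, master, slave, seed=99)


@pytest.fixture(scope="session")
def noiseless_pair():
    """Noiseless linear gain/offset shift between two instruments.

    Useful for exact-recovery oracles: the slave differs from the master
    only by an affine photometric distortion on a coarser grid.
    """
    lib = ComponentLibrary(
        centers=[[1150.0, 1450.0], [1300.0]],
        widths=[[40.0, 55.0], [60.0]],
        amplitudes=[[0.8, 0.6], [0.7]],
        label_coefficients=np.array([60.0, 45.0]),
        label_noise_sd=0.0,
    )
    master = InstrumentProfile(n_channels=60, noise_sd=0.0, name="master")
    slave = InstrumentProfile(n_channels=30, gain=2.0, offset=0.05, noise_sd=0.0,
                              name="slave")
    return generate_paired(40, 40, lib, master, slave, seed=7, paired=True)
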