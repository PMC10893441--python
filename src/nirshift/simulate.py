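"""Synthetic paired-spectrometer benchmark.

Emulates the two-instrument wood-testing setup: a high-resolution master
(512 channels, 1.56 nm resolution) and a coarse OEM slave (118 channels,
6.83 nm), both covering 900–1700 nm. Spectra are Beer–Lambert-style
additive mixtures of Gaussian absorption bands from a small component
library ("cellulose-like", "lignin-like", "hemicellulose-like"); the scalar
label (nominal tensile strength) is a linear function of the component
concentrations plus Gaussian noise.

Each instrument applies, in order: Gaussian instrument-response smoothing
of a given FWHM, a wavelength shift, an affine photometric distortion
(gain, offset, linear baseline), sampling onto its uniform channel grid,
and i.i.d. Gaussian noise. Pure spectra are generated on a dense reference
grid (2048 points, 880–1720 nm) so the convolution error is negligible
relative to the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .spectra import SpectraSet, WavelengthGrid

__all__ = [
    "ComponentLibrary",
    "InstrumentProfile",
    "PairedDataset",
    "default_library",
    "master_profile",
    "slave_profile",
    "reference_grid",
    "simulate_pure_spectrum",
    "apply_instrument",
    "generate_paired",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class ComponentLibrary:
    """Gaussian absorption-band library with a linear label model.

    ``centers[i]``, ``widths[i]``, ``amplitudes[i]`` list the peaks of
    component ``i`` (nm, nm sigma, absorbance). ``label_coefficients``
    maps the concentration vector to the scalar label.
    """

    centers: list
    widths: list
    amplitudes: list
    label_coefficients: np.ndarray
    label_noise_sd: float = 1.0

    def __post_init__(self):
        self.centers = [np.asarray(c, dtype=float) for c in self.centers]
        self.widths = [np.asarray(w, dtype=float) for w in self.widths]
        self.amplitudes = [np.asarray(a, dtype=float) for a in self.amplitudes]
        self.label_coefficients = np.asarray(self.label_coefficients, dtype=float)
        if len(self.centers) == 0:
            raise ValueError("library needs at least one component")
        if len({len(self.centers), len(self.widths), len(self.amplitudes)}) != 1:
            raise ValueError("centers/widths/amplitudes must align per component")
        if self.label_coefficients.size != self.n_components:
            raise ValueError("label_coefficients length must equal n components")
        for w in self.widths:
            if np.any(w <= 0):
                raise ValueError("peak widths must be positive")

    @property
    def n_components(self) -> int:
        return len(self.centers)


@dataclass
class InstrumentProfile:
    """Response model of one spectrometer."""

    n_channels: int
    span: tuple[float, float] = (900.0, 1700.0)
    resolution_fwhm: float = 0.0
    gain: float = 1.0
    offset: float = 0.0
    baseline_slope: float = 0.0  # absorbance per nm
    wavelength_shift: float = 0.0
    noise_sd: float = 0.0
    name: str = "instrument"

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.resolution_fwhm < 0 or self.noise_sd < 0:
            raise ValueError("resolution_fwhm and noise_sd must be non-negative")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.uniform(self.n_channels, *self.span)


@dataclass
class PairedDataset:
    """Master (labeled) / slave (label-held-out) dataset with ground truth."""

    source: SpectraSet
    target: SpectraSet
    concentrations_source: np.ndarray
    concentrations_target: np.ndarray
    target_labels: np.ndarray  # held out; evaluation only
    library: ComponentLibrary
    master: InstrumentProfile
    slave: InstrumentProfile
    seed: int
    paired: bool = False
    # slave renderings of the SAME source samples (transfer standards)
    source_on_slave: SpectraSet | None = field(default=None, repr=False)


def default_library() -> ComponentLibrary:
    """Three wood-like components with 2–3 overtone bands each.

    Peak positions loosely follow the O–H / C–H first-overtone and
    combination regions; positions and amplitudes are synthetic choices,
    not calibrated wood optical constants.
    """
    return ComponentLibrary(
        centers=[[1200.0, 1490.0, 1590.0],  # cellulose-like
                 [1170.0, 1410.0, 1680.0],  # lignin-like
                 [980.0, 1360.0]],          # hemicellulose-like
        widths=[[28.0, 35.0, 40.0],
                [25.0, 45.0, 38.0],
                [30.0, 50.0]],
        amplitudes=[[0.9, 0.7, 0.5],
                    [0.6, 0.8, 0.4],
                    [0.5, 0.6]],
        label_coefficients=np.array([50.0, 40.0, 30.0]),
        label_noise_sd=1.0,
    )


def master_profile() -> InstrumentProfile:
    """High-resolution master (NIRquest512-like): 512 ch, 1.56 nm FWHM."""
    return InstrumentProfile(
        n_channels=512, span=(900.0, 1700.0), resolution_fwhm=1.56,
        gain=1.0, offset=0.0, baseline_slope=0.0, wavelength_shift=0.0,
        noise_sd=0.002, name="master",
    )


def slave_profile() -> InstrumentProfile:
    """Coarse OEM slave: 118 ch, 6.83 nm FWHM, gain/offset/baseline/shift."""
    return InstrumentProfile(
        n_channels=118, span=(900.0, 1700.0), resolution_fwhm=6.83,
        gain=1.25, offset=0.08, baseline_slope=1.5e-4, wavelength_shift=2.0,
        noise_sd=0.004, name="slave",
    )


def reference_grid(n_points: int = 2048, lo: float = 880.0, hi: float = 1720.0) -> WavelengthGrid:
    """Dense uniform grid the pure spectra are rendered on."""
    return WavelengthGrid.uniform(n_points, lo, hi)


def simulate_pure_spectrum(
    concentrations: np.ndarray, library: ComponentLibrary, grid: WavelengthGrid
) -> np.ndarray:
    """Additive Gaussian-band mixture, linear in the concentrations.

    a(λ) = Σ_i c_i Σ_p amp_ip · exp(−(λ−center_ip)² / (2 σ_ip²))
    """
    c = np.asarray(concentrations, dtype=float).ravel()
    if c.size != library.n_components:
        raise ValueError("concentration length must equal n components")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    lam = grid.values
    out = np.zeros_like(lam)
    for ci, centers, widths, amps in zip(
        c, library.centers, library.widths, library.amplitudes
    ):
        for mu, sig, amp in zip(centers, widths, amps):
            out += ci * amp * np.exp(-((lam - mu) ** 2) / (2.0 * sig**2))
    return out


def apply_instrument(
    pure: np.ndarray,
    profile: InstrumentProfile,
    rng: np.random.Generator | None = None,
    reference: WavelengthGrid | None = None,
) -> np.ndarray:
    """Render dense pure spectra through one instrument.

    ``pure`` may be a single spectrum or a matrix of rows on ``reference``
    (default :func:`reference_grid`). Steps: Gaussian response smoothing →
    wavelength shift → gain/offset/baseline → sample onto the instrument
    grid → additive noise.
    """
    reference = reference or reference_grid()
    pure = np.atleast_2d(np.asarray(pure, dtype=float))
    if pure.shape[1] != len(reference):
        raise ValueError("pure spectra must live on the reference grid")
    lo, hi = profile.span
    rlo, rhi = reference.span
    shift = profile.wavelength_shift
    if lo + min(shift, 0.0) < rlo or hi + max(shift, 0.0) > rhi:
        raise ValueError("reference grid does not cover instrument span plus shift")

    dx = reference.values[1] - reference.values[0]
    if profile.resolution_fwhm > 0:
        sigma_samples = profile.resolution_fwhm * _FWHM_TO_SIGMA / dx
        smoothed = gaussian_filter1d(pure, sigma_samples, axis=1, mode="nearest")
    else:
        smoothed = pure

    lam = profile.grid.values
    sample_at = lam + shift  # instrument channel j sees light at λ_j + shift
    out = np.empty((pure.shape[0], profile.n_channels))
    for i in range(pure.shape[0]):
        out[i] = np.interp(sample_at, reference.values, smoothed[i])
    out = profile.gain * out + profile.offset + profile.baseline_slope * (lam - lo)
    if profile.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        out = out + rng.normal(0.0, profile.noise_sd, size=out.shape)
    return out[0] if out.shape[0] == 1 and np.ndim(pure) == 1 else out


def generate_paired(
    n_source: int,
    n_target: int,
    library: ComponentLibrary | None = None,
    master: InstrumentProfile | None = None,
    slave: InstrumentProfile | None = None,
    seed: int = 0,
    paired: bool = False,
) -> PairedDataset:
    """Draw concentrations, render both instruments, attach labels.

    Concentrations are uniform on [0.1, 1.0] per component. The master
    (source) set keeps its labels; the slave (target) set's labels are
    stored separately as evaluation ground truth. ``paired=True`` reuses
    the source concentration draws for the target (sample i corresponds
    across instruments). The source samples are additionally rendered
    through the slave instrument (``source_on_slave``) to serve as
    transfer standards for classical calibration transfer.
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("sample counts must be >= 1")
    library = library or default_library()
    master = master or master_profile()
    slave = slave or slave_profile()
    rng = np.random.default_rng(seed)
    ref = reference_grid()

    k = library.n_components
    conc_s = rng.uniform(0.1, 1.0, size=(n_source, k))
    if paired:
        if n_target != n_source:
            raise ValueError("paired mode requires n_target == n_source")
        conc_t = conc_s.copy()
    else:
        conc_t = rng.uniform(0.1, 1.0, size=(n_target, k))

    pure_s = np.stack([simulate_pure_spectrum(c, library, ref) for c in conc_s])
    pure_t = np.stack([simulate_pure_spectrum(c, library, ref) for c in conc_t])

    abs_s = apply_instrument(pure_s, master, rng, ref)
    abs_t = apply_instrument(pure_t, slave, rng, ref)
    abs_s_on_slave = apply_instrument(pure_s, slave, rng, ref)

    labels_s = conc_s @ library.label_coefficients
    labels_t = conc_t @ library.label_coefficients
    if library.label_noise_sd > 0:
        labels_s = labels_s + rng.normal(0, library.label_noise_sd, n_source)
        labels_t = labels_t + rng.normal(0, library.label_noise_sd, n_target)

    source = SpectraSet(master.grid, abs_s, labels_s, master.name)
    target = SpectraSet(slave.grid, abs_t, None, slave.name)
    standards = SpectraSet(slave.grid, abs_s_on_slave, labels_s, slave.name)
    return PairedDataset(
        source=source,
        target=target,
        concentrations_source=conc_s,
        concentrations_target=conc_t,
        target_labels=labels_t,
        library=library,
        master=master,
        slave=slave,
        seed=seed,
        paired=paired,
        source_on_slave=standards,
    )
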