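"""Spectral containers, CSV I/O, dataset splitting and grid resampling.

All downstream code works with :class:`SpectraSet` — an absorbance matrix on
a strictly increasing wavelength grid (nm), with an optional per-sample
scalar label (tensile strength on the wood task, nominal units here).

The on-disk format is a plain CSV: the header row holds the wavelengths,
optionally followed by a final ``label`` column; each subsequent row is one
sample. Values are written with 17 significant digits so write→read round
trips are lossless at double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "SplitResult",
    "read_spectra_csv",
    "write_spectra_csv",
    "random_split",
    "resample_to_grid",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavelength grid contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    @classmethod
    def uniform(cls, n_channels: int, lo: float, hi: float) -> "WavelengthGrid":
        return cls(np.linspace(lo, hi, n_channels))


@dataclass
class SpectraSet:
    """Absorbance spectra with optional scalar labels.

    Parameters
    ----------
    grid : WavelengthGrid
        Shared wavelength axis of all samples.
    absorbance : ndarray, shape (n_samples, n_channels)
    labels : ndarray, shape (n_samples,), optional
        Reference values (e.g. tensile strength); ``None`` when unlabeled.
    instrument_id : str
        Free-text tag naming the instrument the spectra came from.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    labels: np.ndarray | None = None
    instrument_id: str = ""

    def __post_init__(self):
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=np.float64))
        if self.absorbance.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} channels, "
                f"grid has {len(self.grid)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.float64).ravel()
            if self.labels.size != self.n_samples:
                raise ValueError("labels length must equal n_samples")
            if not np.all(np.isfinite(self.labels)):
                raise ValueError("labels must be finite")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, idx) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(
            self.grid,
            self.absorbance[idx],
            None if self.labels is None else self.labels[idx],
            self.instrument_id,
        )

    def without_labels(self) -> "SpectraSet":
        return SpectraSet(self.grid, self.absorbance.copy(), None, self.instrument_id)


@dataclass
class SplitResult:
    train: SpectraSet
    test: SpectraSet
    ratio: float
    seed: int
    train_idx: np.ndarray = field(default=None, repr=False)
    test_idx: np.ndarray = field(default=None, repr=False)


def read_spectra_csv(path, has_labels: bool | None = None) -> SpectraSet:
    """Read a SpectraSet from CSV.

    The header row gives the wavelengths; a trailing ``label`` column is
    detected automatically when ``has_labels`` is None.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    label_col = cols[-1].strip().lower() == "label" if cols else False
    if has_labels is None:
        has_labels = label_col
    if has_labels and not label_col:
        raise ValueError(f"{path}: expected a final 'label' column")
    wl_cols = cols[:-1] if has_labels else cols
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric wavelength in header: {e}") from e
    if wavelengths.size >= 2 and not np.all(np.diff(wavelengths) > 0):
        raise ValueError(f"{path}: wavelengths in header are not strictly increasing")
    mat = df[wl_cols].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(mat)):
        bad = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"{path}: non-numeric or non-finite value at row {bad[0]}, "
            f"column {wl_cols[bad[1]]}"
        )
    labels = df[cols[-1]].to_numpy(dtype=np.float64) if has_labels else None
    if mat.shape[0] == 0:
        mat = mat.reshape(0, wavelengths.size)
        labels = None if labels is None else labels.reshape(0)
    return SpectraSet(WavelengthGrid(wavelengths), mat, labels, instrument_id=path.stem)


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet to CSV (wavelength header, ≥12 significant digits)."""
    path = Path(path)
    cols = [repr(float(w)) for w in spectra.grid.values]
    data = {c: spectra.absorbance[:, j] for j, c in enumerate(cols)}
    df = pd.DataFrame(data)
    if spectra.labels is not None:
        df["label"] = spectra.labels
    df.to_csv(path, index=False, float_format="%.17g")


def random_split(spectra: SpectraSet, ratio: float, seed: int) -> SplitResult:
    """Seeded random train/test partition.

    ``floor(ratio * n)`` samples go to the training set, the remainder to the
    test set; the permutation comes from ``numpy.random.default_rng(seed)``
    so a fixed seed is bit-reproducible.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0,1), got {ratio}")
    n = spectra.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return SplitResult(
        train=spectra.subset(train_idx),
        test=spectra.subset(test_idx),
        ratio=ratio,
        seed=seed,
        train_idx=train_idx,
        test_idx=test_idx,
    )


def resample_to_grid(spectra: SpectraSet, target: WavelengthGrid) -> SpectraSet:
    """Per-sample linear interpolation onto ``target``; no extrapolation."""
    lo, hi = spectra.grid.span
    tlo, thi = target.span
    if tlo < lo or thi > hi:
        raise ValueError(
            f"target grid [{tlo}, {thi}] extends beyond source span [{lo}, {hi}]"
        )
    out = np.empty((spectra.n_samples, len(target)))
    for i in range(spectra.n_samples):
        out[i] = np.interp(target.values, spectra.grid.values, spectra.absorbance[i])
    labels = None if spectra.labels is None else spectra.labels.copy()
    return SpectraSet(target, out, labels, spectra.instrument_id)
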