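"""Classical calibration-transfer maps: DS, PDS and SST.

All three relate paired transfer standards — the same physical samples
measured on both instruments — by a linear (affine for SST) map from the
slave instrument's channel space to the master's, so a calibration model
built on the master can score corrected slave spectra.

* DS (direct standardization, Wang–Veltkamp–Kowalski): one global
  ridge-regularized least-squares map ``slave @ F ≈ master``.
* PDS (piecewise DS): each master channel is regressed on a small window
  of slave channels around the nearest slave wavelength, giving a banded
  map that is far better conditioned with few standards.
* SST (spectral space transformation, Du et al.): the column-centered
  paired standards ``[master | slave]`` are jointly factored by a
  truncated SVD; new slave spectra are projected onto the slave factor
  and reconstructed in the master space.

DS and SST operate directly on the rectangular slave→master map, so the
two instruments may have different channel counts; PDS matches windows by
nearest wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraSet, WavelengthGrid

__all__ = ["TransferMap", "fit_ds", "fit_pds", "fit_sst", "apply_transfer"]


@dataclass
class TransferMap:
    """Fitted slave→master correction ``corrected = slave @ matrix + intercept``."""

    kind: str  # "DS" | "PDS" | "SST"
    matrix: np.ndarray  # [n_slave_channels, n_master_channels]
    intercept: np.ndarray  # [n_master_channels]
    slave_grid: WavelengthGrid
    master_grid: WavelengthGrid
    meta: dict = field(default_factory=dict)

    def apply(self, slave: SpectraSet) -> SpectraSet:
        return apply_transfer(self, slave)


def _check_paired(master_std: SpectraSet, slave_std: SpectraSet):
    if master_std.n_samples != slave_std.n_samples:
        raise ValueError(
            f"standards must be paired: {master_std.n_samples} master vs "
            f"{slave_std.n_samples} slave samples"
        )
    if master_std.n_samples < 1:
        raise ValueError("need at least one transfer standard")


def _ridge_solve(X: np.ndarray, Y: np.ndarray, ridge: float) -> np.ndarray:
    """Solve min ||X B − Y||² + λ_eff ||B||², λ_eff = ridge·trace(XᵀX)/p."""
    p = X.shape[1]
    G = X.T @ X
    lam = ridge * np.trace(G) / p if p else 0.0
    return np.linalg.solve(G + lam * np.eye(p), X.T @ Y)


def fit_ds(master_std: SpectraSet, slave_std: SpectraSet, ridge: float = 1e-8) -> TransferMap:
    """Direct standardization: one global ridge map slave→master.

    ``ridge`` scales a trace-normalized Tikhonov term; the default keeps
    the solve well-posed when there are fewer standards than slave
    channels (the usual regime at 30–70 % transfer-sample fractions)
    while leaving noiseless full-rank problems essentially exact.
    """
    _check_paired(master_std, slave_std)
    F = _ridge_solve(slave_std.absorbance, master_std.absorbance, ridge)
    return TransferMap(
        kind="DS",
        matrix=F,
        intercept=np.zeros(master_std.n_channels),
        slave_grid=slave_std.grid,
        master_grid=master_std.grid,
        meta={"ridge": ridge, "n_standards": master_std.n_samples},
    )


def fit_pds(
    master_std: SpectraSet,
    slave_std: SpectraSet,
    half_window: int = 5,
    ridge: float = 1e-8,
) -> TransferMap:
    """Piecewise direct standardization with a banded slave→master map.

    For master channel ``j``, the window is the ``2·half_window + 1``
    slave channels centred on the slave channel nearest in wavelength.
    Entries outside each window are exactly zero.
    """
    _check_paired(master_std, slave_std)
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    p_s = slave_std.n_channels
    if half_window > p_s:
        raise ValueError("half_window larger than slave channel count")
    S, M = slave_std.absorbance, master_std.absorbance
    F = np.zeros((p_s, master_std.n_channels))
    nearest = np.array(
        [np.argmin(np.abs(slave_std.grid.values - w)) for w in master_std.grid.values]
    )
    for j, c in enumerate(nearest):
        lo, hi = max(0, c - half_window), min(p_s, c + half_window + 1)
        F[lo:hi, j] = _ridge_solve(S[:, lo:hi], M[:, j], ridge)
    return TransferMap(
        kind="PDS",
        matrix=F,
        intercept=np.zeros(master_std.n_channels),
        slave_grid=slave_std.grid,
        master_grid=master_std.grid,
        meta={
            "ridge": ridge,
            "half_window": half_window,
            "n_standards": master_std.n_samples,
        },
    )


def fit_sst(
    master_std: SpectraSet, slave_std: SpectraSet, n_components: int = 3
) -> TransferMap:
    """Spectral space transformation via a joint truncated SVD.

    The column-centered combined matrix ``Z = [M−m̄ | S−s̄]`` is factored
    ``Z ≈ T [V_mᵀ | V_sᵀ]``; a new slave spectrum is mapped to scores by
    the pseudo-inverse of ``V_sᵀ`` and reconstructed in master space, so
    the affine map is ``F = V_s (V_sᵀV_s)⁻¹ V_mᵀ`` with intercept
    ``m̄ − s̄ F``.
    """
    _check_paired(master_std, slave_std)
    n = master_std.n_samples
    if not 1 <= n_components <= max(n - 1, 1):
        raise ValueError(
            f"n_components must be in [1, n_standards-1], got {n_components}"
        )
    M, S = master_std.absorbance, slave_std.absorbance
    m_bar, s_bar = M.mean(axis=0), S.mean(axis=0)
    Z = np.hstack([M - m_bar, S - s_bar])
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt[:n_components].T  # [(p_m + p_s), k]
    Vm, Vs = V[: M.shape[1]], V[M.shape[1]:]
    F = Vs @ np.linalg.solve(Vs.T @ Vs, Vm.T)
    intercept = m_bar - s_bar @ F
    return TransferMap(
        kind="SST",
        matrix=F,
        intercept=intercept,
        slave_grid=slave_std.grid,
        master_grid=master_std.grid,
        meta={"n_components": n_components, "n_standards": n},
    )


def apply_transfer(tmap: TransferMap, slave: SpectraSet) -> SpectraSet:
    """Correct slave spectra onto the master grid; labels pass through."""
    if slave.n_channels != len(tmap.slave_grid) or not np.allclose(
        slave.grid.values, tmap.slave_grid.values
    ):
        raise ValueError("slave grid does not match the grid the map was fit on")
    corrected = slave.absorbance @ tmap.matrix + tmap.intercept
    if slave.n_samples == 0:
        corrected = corrected.reshape(0, len(tmap.master_grid))
    return SpectraSet(tmap.master_grid, corrected, slave.labels, slave.instrument_id)
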