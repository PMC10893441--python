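"""Metrics and the two benchmark experiment designs.

Metrics are the four the field reports: the coefficient of determination
in percent (R), root-mean-square error (RMSE), its k-fold
cross-validation form (RMSECV, pooled over seeded folds) and its held-out
prediction form (RMSEP).

Two sweeps mirror the study designs:

* :func:`split_ratio_sweep` — train each adaptation method on an
  increasing share of the labeled source data (25 % … 70 %) and score it
  on the target instrument against held-out truth.
* :func:`transfer_sample_sweep` — fit DS/PDS/SST on a growing fraction of
  the paired transfer standards, correct the slave test spectra, and
  score them with one fixed master-domain ridge calibration model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .adapt import DomainAdaptationModel, TransferLossSpec
from .classical import apply_transfer, fit_ds, fit_pds, fit_sst
from .nn import TrainingConfig
from .simulate import PairedDataset
from .spectra import SpectraSet, random_split

__all__ = [
    "EvalReport",
    "r_squared_percent",
    "rmse",
    "rmsep",
    "rmsecv",
    "split_ratio_sweep",
    "transfer_sample_sweep",
    "DEFAULT_SPLIT_RATIOS",
    "DEFAULT_TRANSFER_FRACTIONS",
]

DEFAULT_SPLIT_RATIOS = (0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70)
DEFAULT_TRANSFER_FRACTIONS = (0.3, 0.5, 0.7)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def r_squared_percent(pred, obs) -> float:
    """100·(1 − SS_res/SS_tot); SS_tot about the observed mean."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size or obs.size < 2:
        raise ValueError("pred and obs must share a length >= 2")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R is undefined for constant observations")
    return 100.0 * (1.0 - np.sum((obs - pred) ** 2) / ss_tot)


def rmse(pred, obs) -> float:
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size or pred.size == 0:
        raise ValueError("pred and obs must share a non-zero length")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def rmsep(model, test: SpectraSet, domain: str = "target",
          truth: np.ndarray | None = None) -> float:
    """RMSE of a fitted model's predictions on a held-out test set."""
    obs = truth if truth is not None else test.labels
    if obs is None:
        raise ValueError("test set has no labels and no truth was supplied")
    return rmse(model.predict(test, domain), obs)


def rmsecv(model_factory, data: SpectraSet, k: int = 10, seed: int = 0) -> float:
    """k-fold cross-validated RMSE, pooled over seeded folds.

    ``model_factory(train_set)`` must return an object with
    ``predict(test_set) -> vector`` in label units; each fold's model is
    trained from scratch.
    """
    if data.labels is None:
        raise ValueError("rmsecv needs a labeled dataset")
    n = data.n_samples
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    sq_errors = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        fitted = model_factory(data.subset(np.where(mask)[0]))
        pred = np.asarray(fitted.predict(data.subset(fold))).ravel()
        sq_errors.append((pred - data.labels[fold]) ** 2)
    return float(np.sqrt(np.mean(np.concatenate(sq_errors))))


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-(method, condition, seed) metric rows with a mean ± sd summary."""

    rows: pd.DataFrame
    condition: str  # "split_ratio" | "transfer_fraction"

    def summary(self) -> pd.DataFrame:
        """Mean ± sd of R and RMSEP per (method, condition) cell."""
        g = self.rows.groupby(["method", self.condition])
        out = g.agg(
            R_mean=("R_percent", "mean"),
            R_sd=("R_percent", "std"),
            RMSEP_mean=("RMSEP", "mean"),
            RMSEP_sd=("RMSEP", "std"),
            n_reps=("R_percent", "size"),
        ).reset_index()
        return out

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------


def _adaptation_run(method, source_train, target_train, target_test, truth,
                    config: TrainingConfig) -> tuple[float, float]:
    model = DomainAdaptationModel(source_train, target_train, method=method,
                                  config=config,
                                  loss_spec=TransferLossSpec(method))
    res = model.fit()
    pred = res.predict(target_test, "target")
    return r_squared_percent(pred, truth), rmse(pred, truth)


def split_ratio_sweep(
    methods,
    dataset: PairedDataset,
    ratios=DEFAULT_SPLIT_RATIOS,
    reps: int = 1,
    seed: int = 0,
    config: TrainingConfig | None = None,
    target_test_fraction: float = 0.3,
) -> EvalReport:
    """Train on a share of the source set; score on held-out target samples.

    For each (method, ratio, rep): split the labeled source by ``ratio``
    (the train side is used, echoing the training-set-share design),
    train the adaptation model against the target-train pool, and report
    R / RMSEP on the held-out target test samples with their ground-truth
    labels.
    """
    if any(not 0 < r < 1 for r in ratios):
        raise ValueError("ratios must lie in (0,1)")
    base = config or TrainingConfig()
    target_all = SpectraSet(dataset.target.grid, dataset.target.absorbance,
                            dataset.target_labels, dataset.target.instrument_id)
    tsplit = random_split(target_all, 1.0 - target_test_fraction, seed)
    target_train = tsplit.train.without_labels()
    target_test = tsplit.test.without_labels()
    truth = tsplit.test.labels

    records = []
    for method in methods:
        for ratio in ratios:
            for rep in range(reps):
                rep_seed = seed + 1000 * rep + 17
                split = random_split(dataset.source, ratio, rep_seed)
                cfg = replace(base, seed=rep_seed + sum(ord(c) for c in method))
                r, err = _adaptation_run(method, split.train, target_train,
                                         target_test, truth, cfg)
                records.append({
                    "method": method, "split_ratio": ratio, "seed": rep_seed,
                    "R_percent": r, "RMSE": err, "RMSEP": err,
                })
    return EvalReport(pd.DataFrame(records), "split_ratio")


def transfer_sample_sweep(
    dataset: PairedDataset,
    ct_methods=("DS", "PDS", "SST"),
    fractions=DEFAULT_TRANSFER_FRACTIONS,
    seed: int = 0,
    ridge_alpha: float = 1e-3,
    pds_half_window: int = 5,
    sst_components: int = 5,
    test_fraction: float = 0.3,
) -> EvalReport:
    """DS/PDS/SST accuracy as the transfer-standard share grows.

    A single ridge calibration model is trained once on the master
    spectra; each CT map is fit on the first ``fraction`` share of a
    seeded shuffle of the paired standards, slave test spectra are
    corrected onto the master grid, and the ridge model scores them.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0,1]")
    if dataset.source_on_slave is None:
        raise ValueError("dataset carries no paired transfer standards")

    master_std = dataset.source
    slave_std = dataset.source_on_slave
    n = master_std.n_samples

    # master-domain calibration model, fixed across fractions
    calib = Ridge(alpha=ridge_alpha)
    calib.fit(master_std.absorbance, master_std.labels)

    # held-out slave test samples with truth labels
    target_all = SpectraSet(dataset.target.grid, dataset.target.absorbance,
                            dataset.target_labels, dataset.target.instrument_id)
    tsplit = random_split(target_all, 1.0 - test_fraction, seed)
    slave_test = tsplit.test

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)

    records = []
    for frac in fractions:
        k = max(int(round(frac * n)), 2)
        idx = order[:k]
        m_std, s_std = master_std.subset(idx), slave_std.subset(idx)
        for method in ct_methods:
            if method == "DS":
                tmap = fit_ds(m_std, s_std)
            elif method == "PDS":
                tmap = fit_pds(m_std, s_std, half_window=pds_half_window)
            elif method == "SST":
                ncomp = min(sst_components, k - 1)
                tmap = fit_sst(m_std, s_std, n_components=ncomp)
            else:
                raise ValueError(f"unknown CT method {method!r}")
            corrected = apply_transfer(tmap, slave_test)
            pred = calib.predict(corrected.absorbance)
            records.append({
                "method": method, "transfer_fraction": frac, "seed": seed,
                "n_standards": k,
                "R_percent": r_squared_percent(pred, slave_test.labels),
                "RMSE": rmse(pred, slave_test.labels),
                "RMSEP": rmse(pred, slave_test.labels),
            })
    return EvalReport(pd.DataFrame(records), "transfer_fraction")
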