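"""Standard benchmark experiments on the synthetic two-spectrometer task.

These are the package's headline computations: the transfer-gain
comparison (each adaptation method against its unadapted baseline on the
master→slave task with a gain + resolution + noise shift), the classical
transfer-standard fraction sweep, and the source-share (split-ratio)
sweep. Problem sizes mirror the study's two instruments: 196 labeled
master samples at 512 channels, 270 unlabeled slave samples at 118
channels. Iteration budgets are sized for minutes-scale CPU runs.
"""

from __future__ import annotations

import numpy as np

from .adapt import METHODS, DomainAdaptationModel
from .evaluation import (
    r_squared_percent,
    split_ratio_sweep,
    transfer_sample_sweep,
)
from .nn import TrainingConfig
from .simulate import generate_paired
from .spectra import SpectraSet, random_split

__all__ = [
    "benchmark_config",
    "benchmark_dataset",
    "transfer_gain_benchmark",
    "classical_fraction_benchmark",
    "split_ratio_benchmark",
]


def benchmark_config(seed: int = 0, **overrides) -> TrainingConfig:
    """Desk-scale training budget used by the benchmark experiments."""
    base = dict(iters_warmup=400, iters_adapt=200, iters_joint=500, seed=seed)
    base.update(overrides)
    return TrainingConfig(**base)


def benchmark_dataset(seed: int = 0, n_source: int = 196, n_target: int = 270):
    """The default synthetic master→slave task (gain+resolution+noise shift)."""
    return generate_paired(n_source, n_target, seed=seed)


def transfer_gain_benchmark(seed: int = 0, seeds_per_method: int = 5,
                            methods=METHODS, n_source: int = 196,
                            n_target: int = 270) -> dict:
    """Adapted vs unadapted target-test R per method, median over seeds.

    The unadapted baseline is the supervised source model with the
    private-target layer initialized by the resampled weight copy and no
    transfer training (stage A only).
    """
    ds = benchmark_dataset(seed, n_source, n_target)
    target_all = SpectraSet(ds.target.grid, ds.target.absorbance, ds.target_labels)
    tsplit = random_split(target_all, 0.7, seed + 3)
    tgt_train = tsplit.train.without_labels()
    tgt_test = tsplit.test.without_labels()
    truth = tsplit.test.labels

    out: dict = {}
    for method in methods:
        adapted, baseline = [], []
        for j in range(seeds_per_method):
            cfg = benchmark_config(seed=seed + 11 + j)
            mb = DomainAdaptationModel(ds.source, tgt_train, method=method, config=cfg)
            rb = r_squared_percent(mb.fit(stages="A").predict(tgt_test, "target"), truth)
            ma = DomainAdaptationModel(ds.source, tgt_train, method=method, config=cfg)
            ra = r_squared_percent(ma.fit().predict(tgt_test, "target"), truth)
            adapted.append(ra)
            baseline.append(rb)
        out[method] = {
            "adapted_R": adapted,
            "baseline_R": baseline,
            "adapted_median": float(np.median(adapted)),
            "baseline_median": float(np.median(baseline)),
        }
    return out


def classical_fraction_benchmark(seed: int = 0, fractions=(0.3, 0.5, 0.7),
                                 n_source: int = 196, n_target: int = 270) -> dict:
    """DS/PDS/SST target R as the transfer-standard share grows."""
    ds = benchmark_dataset(seed, n_source, n_target)
    rep = transfer_sample_sweep(ds, fractions=fractions, seed=seed)
    out: dict = {}
    for method in ("DS", "PDS", "SST"):
        rows = rep.rows[rep.rows.method == method].sort_values("transfer_fraction")
        out[method] = {
            "fractions": rows.transfer_fraction.tolist(),
            "R": rows.R_percent.tolist(),
            "RMSEP": rows.RMSEP.tolist(),
        }
    return out


def split_ratio_benchmark(seed: int = 0, ratios=(0.25, 0.7), reps: int = 5,
                          methods=METHODS, n_source: int = 196,
                          n_target: int = 270) -> dict:
    """Mean target R per (method, source-share) cell."""
    ds = benchmark_dataset(seed, n_source, n_target)
    rep = split_ratio_sweep(list(methods), ds, ratios=ratios, reps=reps,
                            seed=seed, config=benchmark_config(seed=seed))
    summary = rep.summary()
    out: dict = {}
    for method in methods:
        cells = summary[summary.method == method].sort_values("split_ratio")
        out[method] = {
            "ratios": cells.split_ratio.tolist(),
            "R_mean": cells.R_mean.tolist(),
            "R_sd": cells.R_sd.tolist(),
        }
    return out
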