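"""Domain-adaptation models: backbone + transfer loss + stage-wise training.

:class:`DomainAdaptationModel` is the user-facing model object, built from
a labeled source (master-instrument) :class:`~nirshift.spectra.SpectraSet`
and an unlabeled target (slave) set; :meth:`DomainAdaptationModel.fit`
runs the three-stage protocol and returns an
:class:`AdaptationResults` carrying the trained weights, the per-iteration
training log and prediction/summary methods.

Training stages (all seeded):

A. Supervised warm-up — private-source + shared + head on source MSE.
B. Private adaptation — with the source-side layers frozen, the
   private-target layer (and shared layer, plus any auxiliary nets) is
   trained on the transfer loss alone; then, with private-target frozen,
   the shared layer and head are refreshed on source batches.
C. Joint fine-tune — total = MSE(source) + λ·transfer, updating
   everything; adversarial parts (CDAN discriminator, MDD auxiliary head,
   ETD critic) follow their min–max rules with a 0→1 coefficient ramp.

The private-target layer starts as a copy of the private-source weights
linearly resampled onto the target channel grid (scaled by the channel
count ratio so dot products keep their magnitude); this gives stage B a
meaningful starting point. Random init is available via the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, RMSProp, Tensor
from .losses import (
    Discriminator,
    LabelHistogram,
    MDDConfig,
    OTConfig,
    SmallMLP,
    build_label_histogram,
    cdan_joint_input,
    histogram_weight,
    median_heuristic_bandwidths,
    mmd,
    etd_loss,
    glot_loss,
    mdd_loss,
    weighted_adversarial_loss,
)
from .nn import Backbone, DenseLayer, LabelScaler, TrainingConfig, mse_loss
from .spectra import SpectraSet

__all__ = [
    "TransferLossSpec",
    "DomainAdaptationModel",
    "AdaptationResults",
    "make_model",
    "train",
    "predict",
    "METHODS",
]

METHODS = ("dan", "cdan", "mdd", "etd", "glot")


@dataclass
class TransferLossSpec:
    """Which transfer loss a model uses, with its hyperparameters."""

    name: str
    histogram_segments: int = 10  # cdan
    mdd: MDDConfig = field(default_factory=MDDConfig)
    ot: OTConfig = field(default_factory=OTConfig)
    glot_local_radius: float = 0.1

    def __post_init__(self):
        if self.name not in METHODS:
            raise ValueError(f"unknown method {self.name!r}; choose from {METHODS}")


class DomainAdaptationModel:
    """One of the five adaptation networks, statsmodels-style.

    Parameters
    ----------
    source : SpectraSet
        Labeled master-instrument spectra.
    target : SpectraSet
        Unlabeled slave-instrument spectra (labels, if present, ignored).
    method : str
        One of ``dan | cdan | mdd | etd | glot``.
    config : TrainingConfig, optional
    loss_spec : TransferLossSpec, optional
    """

    def __init__(self, source: SpectraSet, target: SpectraSet, method: str = "dan",
                 config: TrainingConfig | None = None,
                 loss_spec: TransferLossSpec | None = None):
        if source.labels is None:
            raise ValueError("source set must be labeled")
        self.source = source
        self.target = target.without_labels() if target.labels is not None else target
        self.config = config or TrainingConfig()
        self.loss_spec = loss_spec or TransferLossSpec(method)
        if self.loss_spec.name != method:
            raise ValueError("loss_spec.name disagrees with method")
        self.method = method

        cfg = self.config
        self.backbone = Backbone.build(
            source.n_channels, target.n_channels,
            private_width=cfg.private_width, shared_width=cfg.shared_width,
            dropout_rate=cfg.dropout_rate, seed=cfg.seed,
        )
        self._build_auxiliaries()
        self.histogram: LabelHistogram | None = None
        self._log: list[dict] = []
        self._fitted = False

    # -- wiring --------------------------------------------------------------

    def _build_auxiliaries(self):
        cfg = self.config
        w = cfg.shared_width
        seeds = np.random.SeedSequence(cfg.seed).spawn(3)
        aux_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
        self.discriminator = self.aux_head = None
        if self.method == "cdan":
            self.discriminator = Discriminator(2 * w, width=32, seed=aux_seed[0])
        elif self.method == "mdd":
            rng = np.random.default_rng(aux_seed[0])
            self.aux_head = DenseLayer.init(w, 1, "sigmoid", rng)
        elif self.method == "etd":
            ot = self.loss_spec.ot
            if ot.attention is None:
                ot.attention = SmallMLP(2 * w, 16, 1, seed=aux_seed[1])
            if ot.potential is None:
                ot.potential = SmallMLP(w, 16, 1, seed=aux_seed[2])

    def _aux_params(self) -> list[Tensor]:
        if self.method == "cdan":
            return self.discriminator.params()
        if self.method == "mdd":
            return self.aux_head.params()
        if self.method == "etd":
            return self.loss_spec.ot.attention.params() + self.loss_spec.ot.potential.params()
        return []

    def _make_optimizer(self, params):
        cfg = self.config
        if cfg.optimizer == "adam":
            return Adam(params, lr=cfg.learning_rate,
                        betas=(cfg.momentum, 0.999), weight_decay=cfg.weight_decay)
        return RMSProp(params, lr=cfg.learning_rate, momentum=cfg.momentum)

    # -- transfer loss dispatch ---------------------------------------------

    def _cdan_weights(self, labels_batch, f_t):
        """Histogram weights for both domains; target uses its predictions
        mapped back to label units (pseudo-labels). A configurable floor
        keeps the target term alive while those predictions are still
        rough."""
        scaler = self.backbone.label_scaler
        floor = self.config.cdan_weight_floor
        w_s = np.maximum(histogram_weight(labels_batch, self.histogram), floor)
        w_t = np.maximum(
            histogram_weight(scaler.unscale(f_t.data), self.histogram), floor
        )
        return w_s, w_t

    def _transfer_loss(self, g_s, f_s, g_t, f_t, labels_batch, ramp: float):
        spec = self.loss_spec
        if self.method == "dan":
            kernel = median_heuristic_bandwidths(g_s.data, g_t.data)
            return mmd(g_s, g_t, kernel)
        if self.method == "cdan":
            w_s, w_t = self._cdan_weights(labels_batch, f_t)
            return weighted_adversarial_loss(
                f_s, g_s, f_t, g_t, w_s, w_t, self.discriminator,
                reverse_coeff=ramp,
            )
        if self.method == "mdd":
            # features minimize the disparity against a frozen adversary;
            # the adversary head ascends it on detached features
            aux_s_live = self.aux_head(g_s).reshape(-1)
            aux_t_live = self.aux_head(g_t).reshape(-1)
            disp_feat, _ = mdd_loss(
                f_s, aux_s_live.detach(), f_t, aux_t_live.detach(), spec.mdd
            )
            aux_s = self.aux_head(g_s.detach()).reshape(-1)
            aux_t = self.aux_head(g_t.detach()).reshape(-1)
            _, adv_obj = mdd_loss(f_s.detach(), aux_s, f_t.detach(), aux_t, spec.mdd)
            return spec.mdd.eta * disp_feat + ramp * adv_obj
        if self.method == "etd":
            return etd_loss(g_s, g_t, f_s, f_t, spec.ot)
        if self.method == "glot":
            head_fn = lambda z: self.backbone.head(z).reshape(-1)  # noqa: E731
            return glot_loss(g_s, g_t, head_fn, spec.ot, spec.glot_local_radius)
        raise AssertionError(self.method)

    # -- training ------------------------------------------------------------

    def _init_private_target(self, rng: np.random.Generator):
        cfg = self.config
        if cfg.init_private_target == "random":
            self.backbone.private_target = DenseLayer.init(
                self.target.n_channels, cfg.private_width, "relu", rng
            )
            return
        # column-resample the source private weights onto the target grid
        src_wl = self.source.grid.values
        tgt_wl = self.target.grid.values
        Ws = self.backbone.private_source.W.data
        Wt = np.empty((Ws.shape[0], tgt_wl.size))
        lo, hi = src_wl[0], src_wl[-1]
        probe = np.clip(tgt_wl, lo, hi)
        for r in range(Ws.shape[0]):
            Wt[r] = np.interp(probe, src_wl, Ws[r])
        # match the overall pre-activation scale on the actual (unlabeled)
        # data so the copied layer starts in the backbone's working range:
        # channel counts and standardization differ between instruments, so
        # a purely analytic rescale is unreliable
        mu_s, sd_s = self.backbone.input_stats["source"]
        mu_t, sd_t = self.backbone.input_stats["target"]
        z_s = ((self.source.absorbance - mu_s) / sd_s) @ Ws.T
        z_t = ((self.target.absorbance - mu_t) / sd_t) @ Wt.T
        scale = z_s.std() / max(z_t.std(), 1e-12)
        Wt *= scale
        self.backbone.private_target = DenseLayer(
            Tensor(Wt, requires_grad=True),
            Tensor(self.backbone.private_source.b.data.copy(), requires_grad=True),
            "relu",
        )

    def _batch(self, rng: np.random.Generator, n: int) -> np.ndarray:
        b = self.config.batch_size
        if n <= b:
            return np.arange(n)
        return rng.choice(n, size=b, replace=False)

    def fit(self, stages: str = "ABC") -> "AdaptationResults":
        """Run the stage-wise protocol; ``stages="A"`` is the unadapted
        baseline (supervised warm-up plus the resampled private-target
        copy, no transfer training)."""
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 777]))
        self.backbone.label_scaler = LabelScaler.from_labels(self.source.labels)
        # channel autoscaling: source stats from the labeled source; the
        # target pathway reuses the SOURCE statistics interpolated onto its
        # grid, so instrument shift is left for the network to learn rather
        # than silently removed by preprocessing
        mu_s = self.source.absorbance.mean(0)
        sd_s = self.source.absorbance.std(0) + 1e-12
        src_wl, tgt_wl = self.source.grid.values, self.target.grid.values
        probe = np.clip(tgt_wl, src_wl[0], src_wl[-1])
        self.backbone.input_stats = {
            "source": (mu_s, sd_s),
            "target": (np.interp(probe, src_wl, mu_s), np.interp(probe, src_wl, sd_s)),
        }
        y_scaled = self.backbone.label_scaler.scale(self.source.labels)
        if self.method == "cdan":
            self.histogram = build_label_histogram(
                self.source.labels, self.loss_spec.histogram_segments
            )
        Xs, Xt = self.source, self.target
        n_s, n_t = Xs.n_samples, Xt.n_samples
        self._log = []
        it = 0

        def log(stage, task, transfer, total):
            self._log.append({
                "iteration": len(self._log), "stage": stage,
                "task_loss": task, "transfer_loss": transfer, "total_loss": total,
            })

        # ---- stage A: supervised warm-up on source
        if "A" in stages:
            opt = self._make_optimizer(self.backbone.params(
                ("private_source", "shared", "head")))
            for _ in range(cfg.iters_warmup):
                idx = self._batch(rng, n_s)
                _, f = self.backbone.forward(Xs.absorbance[idx], "source", "train", rng)
                loss = mse_loss(f, Tensor(y_scaled[idx]))
                opt.zero_grad()
                loss.backward()
                opt.step()
                log("A", loss.item(), 0.0, loss.item())

        self._init_private_target(rng)

        # ---- stage B: private adaptation
        if "B" in stages:
            frozen = {id(p): p.data.copy() for p in self.backbone.params(
                ("private_source",))}
            n_b1 = cfg.iters_adapt // 2
            # distribution-matching losses shape the private target layer
            # directly; for the min–max losses stage B instead pre-trains the
            # adversary (discriminator / auxiliary head) on frozen features,
            # leaving the minimax to the task-anchored stage C
            if self.method in ("cdan", "mdd"):
                b1_params = self._aux_params()
            else:
                b1_params = self.backbone.params(("private_target",)) + self._aux_params()
            opt = self._make_optimizer(b1_params)
            for _ in range(n_b1):
                si = self._batch(rng, n_s)
                ti = self._batch(rng, n_t)
                g_s, f_s = self.backbone.forward(Xs.absorbance[si], "source", "train", rng)
                g_t, f_t = self.backbone.forward(Xt.absorbance[ti], "target", "train", rng)
                tloss = self._transfer_loss(g_s, f_s, g_t, f_t, Xs.labels[si], 1.0)
                opt.zero_grad()
                tloss.backward()
                opt.step()
                log("B", 0.0, tloss.item(), tloss.item())
            # refresh the shared trunk and head on source with private layers fixed
            opt = self._make_optimizer(self.backbone.params(("shared", "head")))
            for _ in range(cfg.iters_adapt - n_b1):
                idx = self._batch(rng, n_s)
                _, f = self.backbone.forward(Xs.absorbance[idx], "source", "train", rng)
                loss = mse_loss(f, Tensor(y_scaled[idx]))
                opt.zero_grad()
                loss.backward()
                opt.step()
                log("B", loss.item(), 0.0, loss.item())
            for p in self.backbone.params(("private_source",)):
                assert np.array_equal(p.data, frozen[id(p)]), "freezing contract broken"

        # ---- stage C: joint fine-tune
        if "C" in stages:
            lam = cfg.transfer_loss_weight
            opt = self._make_optimizer(self.backbone.params() + self._aux_params())
            opt_d = (self._make_optimizer(self._aux_params())
                     if self.method == "cdan" else None)
            trunk = self.backbone.params(("private_source", "shared", "head"))
            routed = cfg.route_minimax_to_private and self.method in ("cdan", "mdd")
            for k in range(cfg.iters_joint):
                ramp = (k + 1) / cfg.iters_joint
                si = self._batch(rng, n_s)
                ti = self._batch(rng, n_t)
                g_s, f_s = self.backbone.forward(Xs.absorbance[si], "source", "train", rng)
                g_t, f_t = self.backbone.forward(Xt.absorbance[ti], "target", "train", rng)
                task = mse_loss(f_s, Tensor(y_scaled[si]))
                if lam > 0:
                    if self.method == "cdan":
                        # discriminator step on detached features (Eq.-8 side)
                        w_s, w_t = self._cdan_weights(Xs.labels[si], f_t)
                        e_d = weighted_adversarial_loss(
                            f_s.detach(), g_s.detach(), f_t.detach(), g_t.detach(),
                            w_s, w_t, self.discriminator)
                        opt_d.zero_grad()
                        e_d.backward()
                        opt_d.step()
                        # non-saturating confusion for the features: target
                        # samples push D toward calling them "source"
                        d_t = self.discriminator(cdan_joint_input(f_t, g_t))
                        tloss = -(Tensor(w_t) * d_t.log()).mean() * ramp
                    else:
                        tloss = self._transfer_loss(
                            g_s, f_s, g_t, f_t, Xs.labels[si], ramp)
                    opt.zero_grad()
                    (lam * tloss).backward()
                    if routed:
                        # adversarial gradients shape the instrument-specific
                        # layer only; the trunk stays anchored to the task
                        for p in trunk:
                            p.grad = None
                        if self.method == "cdan":
                            for p in self._aux_params():
                                p.grad = None
                    task.backward()
                    tval = tloss.item()
                    total_val = task.item() + lam * tval
                else:
                    opt.zero_grad()
                    task.backward()
                    tval = 0.0
                    total_val = task.item()
                opt.step()
                log("C", task.item(), tval, total_val)

        self._fitted = True
        return AdaptationResults(self)

    def predict(self, x: SpectraSet, domain: str) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model is not fitted; call fit() first")
        return self.backbone.predict_labels(x, domain)


@dataclass
class AdaptationResults:
    """Fitted adaptation model: predictions, training log, summary."""

    model: DomainAdaptationModel

    @property
    def training_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.model._log)

    def predict(self, x: SpectraSet, domain: str) -> np.ndarray:
        """Eval-mode predictions in label units."""
        return self.model.predict(x, domain)

    def summary(self) -> str:
        m = self.model
        log = self.training_log
        lines = [
            "Domain adaptation results",
            "=" * 48,
            f"method:            {m.method}",
            f"optimizer:         {m.config.optimizer} (lr={m.config.learning_rate})",
            f"transfer weight λ: {m.config.transfer_loss_weight}",
            f"source:            {m.source.n_samples} × {m.source.n_channels} ch "
            f"({m.source.instrument_id or 'source'})",
            f"target:            {m.target.n_samples} × {m.target.n_channels} ch "
            f"({m.target.instrument_id or 'target'})",
            f"iterations:        {len(log)}",
        ]
        if len(log):
            tail = log.tail(50)
            lines.append(f"final task MSE (scaled, mean of last 50 it): "
                         f"{tail['task_loss'].mean():.6f}")
            lines.append(f"final transfer loss (mean of last 50 it):    "
                         f"{tail['transfer_loss'].mean():.6f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def make_model(name: str, shapes: tuple[int, int], config: TrainingConfig | None = None,
               source: SpectraSet | None = None, target: SpectraSet | None = None,
               loss_spec: TransferLossSpec | None = None) -> DomainAdaptationModel:
    """Build one of the five models for (n_source_channels, n_target_channels).

    When ``source``/``target`` are omitted, empty placeholder sets of the
    right widths are created; pass the real data to :func:`train`.
    """
    if name not in METHODS:
        raise ValueError(f"unknown method {name!r}; choose from {METHODS}")
    n_sc, n_tc = shapes
    if source is None or target is None:
        raise ValueError("make_model requires source and target SpectraSets")
    if source.n_channels != n_sc or target.n_channels != n_tc:
        raise ValueError("shapes disagree with the provided SpectraSets")
    return DomainAdaptationModel(source, target, method=name, config=config,
                                 loss_spec=loss_spec)


def train(model: DomainAdaptationModel, source: SpectraSet | None = None,
          target: SpectraSet | None = None, stages: str = "ABC") -> AdaptationResults:
    if source is not None:
        if source.labels is None:
            raise ValueError("source set must be labeled")
        if source.n_channels != model.source.n_channels:
            raise ValueError("source channel count does not match the model")
        model.source = source
    if target is not None:
        if target.n_channels != model.target.n_channels:
            raise ValueError("target channel count does not match the model")
        model.target = target.without_labels() if target.labels is not None else target
    return model.fit(stages=stages)


def predict(model: DomainAdaptationModel, x: SpectraSet, domain: str) -> np.ndarray:
    return model.predict(x, domain)
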