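"""Dense private/shared regression backbone.

The feature extractor deliberately contains no convolution or pooling:
NIR absorbance channels map linearly onto functional-group bands, so the
network is a stack of fully connected layers — an instrument-specific
("private") input layer per domain, a shared middle layer, and a one-unit
sigmoid regression head — with dropout between layers standing in for
pooling as the overfitting control. Hidden activations are ReLU.

Because the head is a sigmoid, labels are affinely mapped into the
[0.05, 0.95] band of (0, 1) for training and mapped back for reporting;
the margin keeps targets away from the saturated tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor
from .spectra import SpectraSet

__all__ = [
    "DenseLayer",
    "LabelScaler",
    "Backbone",
    "TrainingConfig",
    "dense_forward",
    "mse_loss",
    "scale_labels",
    "unscale_predictions",
]

_ACTIVATIONS = ("relu", "sigmoid", "identity")


@dataclass
class DenseLayer:
    """One fully connected layer h = activation(W·y + b)."""

    W: Tensor
    b: Tensor
    activation: str = "identity"

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not isinstance(self.W, Tensor):
            self.W = Tensor(self.W, requires_grad=True)
        if not isinstance(self.b, Tensor):
            self.b = Tensor(self.b, requires_grad=True)
        if self.W.data.ndim != 2 or self.b.data.ndim != 1:
            raise ValueError("W must be 2-D [out, in] and b 1-D [out]")
        if self.W.data.shape[0] != self.b.data.shape[0]:
            raise ValueError("W row count must match b length")
        if not (np.all(np.isfinite(self.W.data)) and np.all(np.isfinite(self.b.data))):
            raise ValueError("layer parameters must be finite")

    @property
    def n_in(self) -> int:
        return self.W.data.shape[1]

    @property
    def n_out(self) -> int:
        return self.W.data.shape[0]

    def params(self) -> list[Tensor]:
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return dense_forward(x, self)

    @classmethod
    def init(cls, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        """Seeded Glorot-uniform initialization."""
        bound = np.sqrt(6.0 / (n_in + n_out))
        W = rng.uniform(-bound, bound, size=(n_out, n_in))
        return cls(Tensor(W, requires_grad=True),
                   Tensor(np.zeros(n_out), requires_grad=True), activation)


def dense_forward(y, layer: DenseLayer):
    """h = g(W·y + b) for a single vector or a batch of row vectors."""
    t = as_tensor(y)
    was_tensor = isinstance(y, Tensor)
    if t.data.ndim == 1:
        if t.data.shape[0] != layer.n_in:
            raise ValueError(f"input length {t.data.shape[0]} != layer.in {layer.n_in}")
        z = layer.W @ t + layer.b
    else:
        if t.data.shape[1] != layer.n_in:
            raise ValueError(f"input width {t.data.shape[1]} != layer.in {layer.n_in}")
        z = t @ layer.W.T + layer.b
    if layer.activation == "relu":
        z = z.relu()
    elif layer.activation == "sigmoid":
        z = z.sigmoid()
    return z if was_tensor else z.data


@dataclass(frozen=True)
class LabelScaler:
    """Affine map from [min, max] label units onto [0.05, 0.95]."""

    lo: float
    hi: float
    band: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self):
        if not self.hi > self.lo:
            raise ValueError("scaler requires max > min")

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelScaler":
        return cls(float(np.min(labels)), float(np.max(labels)))

    def scale(self, labels):
        a, b = self.band
        return a + (np.asarray(labels, dtype=float) - self.lo) * (b - a) / (self.hi - self.lo)

    def unscale(self, pred):
        a, b = self.band
        return self.lo + (np.asarray(pred, dtype=float) - a) * (self.hi - self.lo) / (b - a)


def scale_labels(labels, scaler: LabelScaler):
    return scaler.scale(labels)


def unscale_predictions(pred, scaler: LabelScaler):
    return scaler.unscale(pred)


@dataclass
class Backbone:
    """Private-source / shared / private-target trunk with a sigmoid head.

    ``forward(x, domain=...)`` routes a batch through the private layer of
    that domain, dropout, the shared layer, dropout, and the head. The
    shared-layer activations are the features ``g`` the transfer losses
    align; the head output is the prediction ``f`` in (0, 1).
    """

    private_source: DenseLayer
    private_target: DenseLayer
    shared: DenseLayer
    head: DenseLayer
    dropout_rate: float = 0.2
    label_scaler: LabelScaler | None = None
    # per-domain channel autoscaling (mu, sd), set once at training start;
    # NIR channels are strongly collinear and strictly positive, so
    # centring/scaling per instrument is essential for the optimizer
    input_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.private_source.n_out != self.shared.n_in:
            raise ValueError("private_source.out must equal shared.in")
        if self.private_target.n_out != self.shared.n_in:
            raise ValueError("private_target.out must equal shared.in")
        if self.head.n_out != 1:
            raise ValueError("head must have a single output unit")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @classmethod
    def build(
        cls,
        n_source_channels: int,
        n_target_channels: int,
        private_width: int = 64,
        shared_width: int = 32,
        dropout_rate: float = 0.2,
        seed: int = 0,
    ) -> "Backbone":
        rng = np.random.default_rng(seed)
        return cls(
            private_source=DenseLayer.init(n_source_channels, private_width, "relu", rng),
            private_target=DenseLayer.init(n_target_channels, private_width, "relu", rng),
            shared=DenseLayer.init(private_width, shared_width, "relu", rng),
            head=DenseLayer.init(shared_width, 1, "sigmoid", rng),
            dropout_rate=dropout_rate,
        )

    def params(self, parts=("private_source", "private_target", "shared", "head")):
        out: list[Tensor] = []
        for name in parts:
            out.extend(getattr(self, name).params())
        return out

    def _dropout(self, x: Tensor, mode: str, rng: np.random.Generator | None) -> Tensor:
        if mode != "train" or self.dropout_rate == 0.0:
            return x
        if rng is None:
            raise ValueError("rng required for dropout in train mode")
        keep = 1.0 - self.dropout_rate
        mask = (rng.random(x.data.shape) < keep) / keep  # inverted dropout
        return x * Tensor(mask)

    def forward(
        self,
        x: SpectraSet | np.ndarray,
        domain: str,
        mode: str = "eval",
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Return (features g [n × shared_width], predictions f [n] in (0,1))."""
        if domain not in ("source", "target"):
            raise ValueError(f"domain must be 'source' or 'target', got {domain!r}")
        if mode not in ("train", "eval"):
            raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
        mat = x.absorbance if isinstance(x, SpectraSet) else np.atleast_2d(x)
        if domain in self.input_stats:
            mu, sd = self.input_stats[domain]
            mat = (mat - mu) / sd
        private = self.private_source if domain == "source" else self.private_target
        if mat.shape[1] != private.n_in:
            raise ValueError(
                f"{domain} input has {mat.shape[1]} channels, private layer "
                f"expects {private.n_in}"
            )
        h = private(Tensor(mat))
        h = self._dropout(h, mode, rng)
        g = self.shared(h)
        g_dropped = self._dropout(g, mode, rng)
        f = self.head(g_dropped).reshape(-1)
        return g, f

    def predict_labels(self, x, domain: str) -> np.ndarray:
        """Deterministic eval-mode predictions in label units."""
        if self.label_scaler is None:
            raise ValueError("backbone has no label scaler; train first")
        _, f = self.forward(x, domain, mode="eval")
        return self.label_scaler.unscale(f.data)


def mse_loss(pred, target):
    """Mean squared error; the task loss replacing cross-entropy."""
    p = as_tensor(pred)
    t = as_tensor(target)
    if p.data.size == 0:
        raise ValueError("mse_loss on empty vectors")
    if p.data.shape != t.data.shape:
        raise ValueError("pred and target must share a shape")
    out = ((p - t) ** 2).mean()
    return out if isinstance(pred, Tensor) or isinstance(target, Tensor) else out.item()


@dataclass
class TrainingConfig:
    """Optimization settings for the adaptation trainer.

    Defaults follow the study's printed settings: learning rate 1e-3 for
    both optimizers, RMSProp momentum 0.9, Adam β1 0.9 with weight decay
    0.01, transfer-loss weight λ = 0.1. Iteration budgets are sized for
    minutes-scale CPU runs and are freely overridable.
    """

    optimizer: str = "adam"  # "adam" | "rmsprop"
    learning_rate: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 0.01
    transfer_loss_weight: float = 0.1
    batch_size: int = 32
    iters_warmup: int = 2000  # stage A
    iters_adapt: int = 1000   # stage B
    iters_joint: int = 2000   # stage C
    dropout_rate: float = 0.2
    private_width: int = 64
    shared_width: int = 32
    seed: int = 0
    init_private_target: str = "resample"  # "resample" | "random"
    # stabilizers for the min–max losses (CDAN, MDD): keep their transfer
    # gradient off the shared trunk, and floor the CDAN histogram weights
    # during training so the target term cannot silently vanish
    route_minimax_to_private: bool = True
    cdan_weight_floor: float = 0.2

    def __post_init__(self):
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.transfer_loss_weight < 0:
            raise ValueError("transfer_loss_weight must be >= 0")
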