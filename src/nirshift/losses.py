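"""Transfer losses for unsupervised domain adaptation of spectral regressors.

Five losses are provided, each a scalar discrepancy between source- and
target-domain batches that the trainer adds to the supervised task loss:

* :func:`mmd` — (multi-kernel) maximum mean discrepancy, the biased
  V-statistic estimate averaged over a Gaussian bandwidth set.
* :func:`weighted_adversarial_loss` — a conditional domain-adversarial
  objective whose discriminator sees the outer product of predictions and
  features, with per-sample weights from a label histogram: segments of
  the label range holding more training labels get weight up to 1, the
  emptiest segment weight 0.
* :func:`mdd_loss` — margin disparity discrepancy adapted to regression:
  an auxiliary head maximizes the squared main/auxiliary disagreement on
  the target relative to γ times the source disagreement.
* :func:`etd_loss` — entropic optimal transport over a joint
  feature-plus-prediction cost, attention-reweighted per pair, with a
  Kantorovich potential network as an adversarial critic regularizer.
* :func:`glot_loss` — a global entropic OT term between feature clouds
  plus a local distributional-robustness term: the squared prediction
  change under a worst-case feature perturbation inside an L2 ball,
  approximated by one gradient-ascent step.

All losses accept either plain numpy arrays (returning floats, handy in
tests) or autodiff :class:`~nirshift.autodiff.Tensor` batches (returning
a Tensor the trainer backpropagates through).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .autodiff import Tensor, as_tensor, concat, grad_reverse
from .nn import DenseLayer

__all__ = [
    "KernelSpec",
    "median_heuristic_bandwidths",
    "mmd",
    "LabelHistogram",
    "build_label_histogram",
    "histogram_weight",
    "SmallMLP",
    "Discriminator",
    "cdan_joint_input",
    "weighted_adversarial_loss",
    "MDDConfig",
    "mdd_loss",
    "OTConfig",
    "sinkhorn_plan",
    "etd_loss",
    "glot_loss",
]


# ---------------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and bandwidth set for MK-MMD.

    ``family`` is ``"gaussian"`` (k(x,y)=exp(−‖x−y‖²/2σ²)) or ``"linear"``
    (k(x,y)=x·y, a test-only kernel whose MMD has the closed form
    ‖mean_s − mean_t‖²). Bandwidths are the σ values of the multi-kernel
    set; the estimator averages over them.
    """

    family: str = "gaussian"
    bandwidths: tuple = (1.0,)

    def __post_init__(self):
        if self.family not in ("gaussian", "linear"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian":
            if len(self.bandwidths) == 0 or any(b <= 0 for b in self.bandwidths):
                raise ValueError("bandwidths must be positive and non-empty")


def median_heuristic_bandwidths(
    xs: np.ndarray, xt: np.ndarray, factors=(0.25, 0.5, 1.0, 2.0, 4.0)
) -> KernelSpec:
    """Multi-kernel set: the median pairwise distance times a factor ladder."""
    pooled = np.vstack([np.atleast_2d(xs), np.atleast_2d(xt)])
    d2 = _sq_dists_np(pooled, pooled)
    med = np.sqrt(np.median(d2[np.triu_indices_from(d2, k=1)]))
    med = med if med > 0 else 1.0
    return KernelSpec("gaussian", tuple(med * f for f in factors))


def _sq_dists_np(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return (
        (X**2).sum(axis=1)[:, None] + (Y**2).sum(axis=1)[None, :] - 2.0 * X @ Y.T
    )


def _sq_dists(X: Tensor, Y: Tensor) -> Tensor:
    xn = (X * X).sum(axis=1, keepdims=True)  # [n,1]
    yn = (Y * Y).sum(axis=1, keepdims=True)  # [m,1]
    return xn + yn.T - 2.0 * (X @ Y.T)


def mmd(features_s, features_t, kernel: KernelSpec = None):
    """Biased squared-MMD estimate between two feature batches (≥ 0).

    Averages the three kernel-mean terms k̄ss + k̄tt − 2k̄st over the
    kernel set; clamped at zero so roundoff cannot produce a negative
    discrepancy.
    """
    is_tensor = isinstance(features_s, Tensor) or isinstance(features_t, Tensor)
    Xs, Xt = as_tensor(features_s), as_tensor(features_t)
    if Xs.data.ndim == 1:
        Xs = Xs.reshape(-1, 1)
    if Xt.data.ndim == 1:
        Xt = Xt.reshape(-1, 1)
    if Xs.data.shape[1] != Xt.data.shape[1]:
        raise ValueError("feature dimensions differ between domains")
    if Xs.data.shape[0] < 1 or Xt.data.shape[0] < 1:
        raise ValueError("need at least one sample per domain")
    if kernel is None:
        kernel = median_heuristic_bandwidths(Xs.data, Xt.data)

    if kernel.family == "linear":
        mean_s = Xs.mean(axis=0)
        mean_t = Xt.mean(axis=0)
        diff = mean_s - mean_t
        out = (diff * diff).sum()
    else:
        dss = _sq_dists(Xs, Xs)
        dtt = _sq_dists(Xt, Xt)
        dst = _sq_dists(Xs, Xt)
        total = None
        for sigma in kernel.bandwidths:
            c = -1.0 / (2.0 * sigma**2)
            term = (dss * c).exp().mean() + (dtt * c).exp().mean() - 2.0 * (dst * c).exp().mean()
            total = term if total is None else total + term
        out = total * (1.0 / len(kernel.bandwidths))
    out = out.clamp(0.0, np.inf)
    return out if is_tensor else float(out.data)


# ---------------------------------------------------------------------------
# Label histogram weighting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelHistogram:
    """Uniform partition of the label range with segment probabilities."""

    R_n: float
    R_m: float
    N: int
    counts: np.ndarray
    num_label: int
    p: np.ndarray

    @property
    def p_min(self) -> float:
        return float(self.p.min())

    @property
    def p_max(self) -> float:
        return float(self.p.max())

    def segment_of(self, values) -> np.ndarray:
        """Segment index per value; values outside clamp to the ends."""
        v = np.asarray(values, dtype=float)
        if self.R_m == self.R_n:
            return np.zeros(v.shape, dtype=int)
        k = np.floor((v - self.R_n) / (self.R_m - self.R_n) * self.N).astype(int)
        return np.clip(k, 0, self.N - 1)


def build_label_histogram(labels, N: int = 10, value_range=None) -> LabelHistogram:
    """Divide [R_n, R_m] into N equal segments and count labels per segment.

    Segments are half-open [lo, hi) with the last segment closed;
    ``value_range`` overrides the (min, max) taken from the labels.
    """
    labels = np.asarray(labels, dtype=float).ravel()
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if N < 1:
        raise ValueError("N must be >= 1")
    if value_range is None:
        R_n, R_m = float(labels.min()), float(labels.max())
    else:
        R_n, R_m = map(float, value_range)
    if R_m < R_n:
        raise ValueError("range max must be >= min")
    if R_m == R_n:
        counts = np.zeros(N, dtype=int)
        counts[0] = labels.size
    else:
        edges = R_n + (R_m - R_n) * np.arange(N + 1) / N
        k = np.clip(
            np.floor((labels - R_n) / (R_m - R_n) * N).astype(int), 0, N - 1
        )
        counts = np.bincount(k[(labels >= R_n) & (labels <= R_m)], minlength=N)
        del edges
    return LabelHistogram(
        R_n=R_n, R_m=R_m, N=N, counts=counts,
        num_label=int(counts.sum()), p=counts / max(counts.sum(), 1),
    )


def histogram_weight(g_value, hist: LabelHistogram):
    """Weight w(g) = (p(r_k) − p_min) / (p_max − p_min) for g's segment.

    Total on the label axis: out-of-range values clamp to the nearest
    segment, and a flat histogram (p_max = p_min) gives w ≡ 1 — with no
    density information nobody should be down-weighted.
    """
    scalar = np.isscalar(g_value) or np.ndim(g_value) == 0
    k = hist.segment_of(g_value)
    if hist.p_max == hist.p_min:
        w = np.ones_like(np.asarray(k, dtype=float))
    else:
        w = (hist.p[k] - hist.p_min) / (hist.p_max - hist.p_min)
    return float(w) if scalar else w


# ---------------------------------------------------------------------------
# Small auxiliary networks
# ---------------------------------------------------------------------------


class SmallMLP:
    """Two-layer dense network used for the auxiliary heads and critics."""

    def __init__(self, n_in: int, width: int, n_out: int,
                 out_activation: str = "identity", seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden = DenseLayer.init(n_in, width, "relu", rng)
        self.out = DenseLayer.init(width, n_out, out_activation, rng)

    def params(self) -> list[Tensor]:
        return self.hidden.params() + self.out.params()

    def __call__(self, x: Tensor) -> Tensor:
        return self.out(self.hidden(as_tensor(x)))


class Discriminator(SmallMLP):
    """Domain discriminator on the joint (prediction × feature) input.

    Sigmoid output clamped to [1e-6, 1−1e-6] so the adversarial log terms
    stay finite.
    """

    CLAMP = 1e-6

    def __init__(self, n_in: int, width: int = 32, seed: int = 0):
        super().__init__(n_in, width, 1, out_activation="sigmoid", seed=seed)

    def __call__(self, x: Tensor) -> Tensor:
        d = super().__call__(x).reshape(-1)
        return d.clamp(self.CLAMP, 1.0 - self.CLAMP)


def cdan_joint_input(f, g):
    """Outer-product conditioning of the discriminator input.

    For a scalar regression output f ∈ (0,1) and feature row g, the
    flattened conditioning is [g·f, g·(1−f)] — the two-bin analogue of the
    classifier outer product, preserving ‖·‖₁ = ‖g‖₁ for f ∈ [0,1].
    """
    is_tensor = isinstance(f, Tensor) or isinstance(g, Tensor)
    ft, gt = as_tensor(f), as_tensor(g)
    if gt.data.ndim == 1:
        gt = gt.reshape(1, -1)
    fcol = ft.reshape(-1, 1)
    joint = concat([gt * fcol, gt * (1.0 - fcol)], axis=1)
    return joint if is_tensor else joint.data


def weighted_adversarial_loss(f_s, g_s, f_t, g_t, weights_s, weights_t,
                              D: Discriminator, reverse_coeff: float | None = None):
    """Histogram-weighted conditional adversarial objective.

    E′(D,G) = −mean_s[w·log D(f,g)] − mean_t[w·log(1−D(f,g))], the
    standard two-sided GAN form. ``reverse_coeff`` inserts a gradient
    reversal between the (f,g) inputs and the discriminator so one
    optimizer trains D to discriminate while the features learn to
    confuse it.
    """
    w_s = np.asarray(weights_s, dtype=float).ravel()
    w_t = np.asarray(weights_t, dtype=float).ravel()
    f_s, f_t = as_tensor(f_s), as_tensor(f_t)
    if w_s.size != f_s.data.size or w_t.size != f_t.data.size:
        raise ValueError("weight length must match the sample count per domain")
    joint_s = cdan_joint_input(f_s, as_tensor(g_s))
    joint_t = cdan_joint_input(f_t, as_tensor(g_t))
    if reverse_coeff is not None:
        joint_s = grad_reverse(joint_s, reverse_coeff)
        joint_t = grad_reverse(joint_t, reverse_coeff)
    d_s = D(joint_s)
    d_t = D(joint_t)
    loss = -(Tensor(w_s) * d_s.log()).mean() - (Tensor(w_t) * (1.0 - d_t).log()).mean()
    return loss


# ---------------------------------------------------------------------------
# MDD
# ---------------------------------------------------------------------------


@dataclass
class MDDConfig:
    """Margin disparity settings: margin γ ≥ 1, tradeoff η > 0."""

    gamma: float = 4.0
    eta: float = 1.0

    def __post_init__(self):
        if self.gamma < 1.0:
            raise ValueError("margin gamma must be >= 1")
        if self.eta <= 0.0:
            raise ValueError("tradeoff eta must be > 0")


def mdd_loss(main_pred_s, aux_pred_s, main_pred_t, aux_pred_t, cfg: MDDConfig):
    """Regression margin disparity.

    disparity = mean_t[(f′−f)²] − γ·mean_s[(f′−f)²]; the auxiliary head
    f′ maximizes it (returned adversary objective is its negation) while
    the main network minimizes source MSE + η·disparity.
    """
    ms, as_, mt, at = map(as_tensor, (main_pred_s, aux_pred_s, main_pred_t, aux_pred_t))
    if ms.data.shape != as_.data.shape or mt.data.shape != at.data.shape:
        raise ValueError("main/auxiliary prediction lengths must align per domain")
    disparity = ((at - mt) ** 2).mean() - cfg.gamma * ((as_ - ms) ** 2).mean()
    adversary_objective = -disparity
    if not (isinstance(main_pred_s, Tensor) or isinstance(main_pred_t, Tensor)):
        return float(disparity.data), float(adversary_objective.data)
    return disparity, adversary_objective


# ---------------------------------------------------------------------------
# Optimal transport: Sinkhorn, ETD, GLOT
# ---------------------------------------------------------------------------


@dataclass
class OTConfig:
    """Entropic OT settings plus the ETD auxiliary networks."""

    epsilon: float = 0.05
    sinkhorn_iterations: int = 50
    attention: SmallMLP | None = None
    potential: SmallMLP | None = None
    critic_weight: float = 0.1

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("entropic regularization epsilon must be > 0")
        if self.sinkhorn_iterations < 1:
            raise ValueError("sinkhorn_iterations must be >= 1")


def sinkhorn_plan(cost: np.ndarray, epsilon: float, iterations: int = 200) -> np.ndarray:
    """Entropic-regularized OT plan between uniform marginals.

    Log-domain Sinkhorn: rows of the returned plan sum to 1/n_s and
    columns to 1/n_t (total mass 1). Stable for small ε.
    """
    C = np.asarray(cost, dtype=float)
    if C.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if not np.all(np.isfinite(C)):
        raise ValueError("cost must be finite")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    n_s, n_t = C.shape
    log_a = np.full(n_s, -np.log(n_s))
    log_b = np.full(n_t, -np.log(n_t))
    f = np.zeros(n_s)
    g = np.zeros(n_t)
    for _ in range(iterations):
        f = epsilon * (log_a - logsumexp((g[None, :] - C) / epsilon, axis=1))
        g = epsilon * (log_b - logsumexp((f[:, None] - C) / epsilon, axis=0))
    return np.exp((f[:, None] + g[None, :] - C) / epsilon)


def _joint_cost(features_s, features_t, preds_s, preds_t):
    Fs, Ft = as_tensor(features_s), as_tensor(features_t)
    if Fs.data.shape[1] != Ft.data.shape[1]:
        raise ValueError("feature dimensions differ between domains")
    cost = _sq_dists(Fs, Ft)
    if preds_s is not None:
        ps = as_tensor(preds_s).reshape(-1, 1)
        pt = as_tensor(preds_t).reshape(1, -1)
        d = ps - pt
        cost = cost + d * d
    return cost


def etd_loss(features_s, features_t, preds_s, preds_t, cfg: OTConfig):
    """Attention-reweighted entropic transport cost with a critic term.

    cost_ij = ‖g_i − g_j‖² + (f_i − f_j)², multiplied per pair by the
    attention network's softplus score normalized to mean 1 (attention ≡ 1
    when no network is configured, reducing to plain entropic OT). The
    plan comes from :func:`sinkhorn_plan` on the detached reweighted cost.
    When a Kantorovich potential network is configured it acts as a
    critic: it ascends mean_s[g(feat)] − mean_t[g(feat)] while (through
    gradient reversal) the features descend it.
    """
    is_tensor = isinstance(features_s, Tensor) or isinstance(features_t, Tensor)
    cost = _joint_cost(features_s, features_t, preds_s, preds_t)
    n_s, n_t = cost.data.shape

    if cfg.attention is not None:
        Fs, Ft = as_tensor(features_s), as_tensor(features_t)
        d = Fs.data.shape[1]
        pairs = np.empty((n_s * n_t, 2 * d))
        pairs[:, :d] = np.repeat(Fs.data, n_t, axis=0)
        pairs[:, d:] = np.tile(Ft.data, (n_s, 1))
        raw = cfg.attention(Tensor(pairs)).reshape(n_s, n_t).softplus()
        att = raw / raw.mean().clamp(1e-12, np.inf)
    else:
        att = Tensor(np.ones((n_s, n_t)))

    weighted_cost = att * cost
    plan = sinkhorn_plan(
        np.maximum(weighted_cost.data, 0.0), cfg.epsilon, cfg.sinkhorn_iterations
    )
    loss = (Tensor(plan) * weighted_cost).sum()

    if cfg.potential is not None:
        fs_r = grad_reverse(as_tensor(features_s), 1.0)
        ft_r = grad_reverse(as_tensor(features_t), 1.0)
        dual = cfg.potential(fs_r).mean() - cfg.potential(ft_r).mean()
        # minimizing −dual trains the critic to ascend the dual while the
        # reversed features descend it
        loss = loss + cfg.critic_weight * (-dual)
    return loss if is_tensor else float(loss.data)


def glot_loss(features_s, features_t, head=None, cfg: OTConfig = None,
              local_radius: float = 0.0):
    """Global OT alignment plus a local perturbation-robustness term.

    Global: entropic OT distance between the feature clouds on squared
    Euclidean cost. Local: the squared prediction change of ``head`` under
    the worst feature perturbation in an L2 ball of ``local_radius``,
    approximated by one ascent step along the input gradient (computed in
    a detached side graph, then applied as a fixed perturbation — exact
    for a linear head).
    """
    if local_radius < 0:
        raise ValueError("local_radius must be >= 0")
    cfg = cfg or OTConfig()
    is_tensor = isinstance(features_s, Tensor) or isinstance(features_t, Tensor)
    cost = _joint_cost(features_s, features_t, None, None)
    plan = sinkhorn_plan(
        np.maximum(cost.data, 0.0), cfg.epsilon, cfg.sinkhorn_iterations
    )
    loss = (Tensor(plan) * cost).sum()

    if local_radius > 0 and head is not None:
        Fs = as_tensor(features_s)
        # ascent direction from a detached side graph
        probe = Tensor(Fs.data.copy(), requires_grad=True)
        head(probe).sum().backward()
        grad = probe.grad if probe.grad is not None else np.zeros_like(Fs.data)
        norms = np.linalg.norm(grad, axis=-1, keepdims=True)
        direction = np.where(norms > 0, grad / np.maximum(norms, 1e-300), 0.0)
        delta = Tensor(local_radius * direction)
        shift = head(Fs + delta) - head(Fs)
        loss = loss + (shift * shift).mean()
    return loss if is_tensor else float(loss.data)
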