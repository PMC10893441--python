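# Methods

`nirshift` implements calibration transfer (CT) for near-infrared (NIR)
spectral regression: a model trained on a *master* spectrometer is adapted
so it predicts correctly from spectra measured on a *slave* instrument with
a different channel count, resolution and photometric response, without new
reference chemistry on the slave. Two families are provided — unsupervised
domain-adaptation networks and the classical DS/PDS/SST standardization
maps — together with a synthetic paired-spectrometer generator that makes
the whole pipeline testable end to end.

## The regression backbone

NIR absorbance channels relate near-linearly to functional-group
concentrations, so the feature extractor deliberately avoids convolution
and pooling. The network is

```
private input layer (per instrument) → dropout → shared layer → dropout → sigmoid head
```

with ReLU hidden activations. The private-source layer takes the master's
channels (default 512), the private-target layer the slave's (default 118);
both feed the same shared trunk, which is how instruments of different
dimensionality share one calibration. Dropout (default rate 0.2) is the
overfitting control in place of pooling. Because the head is a sigmoid,
labels are affinely mapped onto [0.05, 0.95] for training and mapped back
for reporting; the margin keeps targets off the saturated tails. Defaults:
private width 64, shared width 32, Glorot-uniform seeded init, Adam
(lr 1e-3, β₁ 0.9, weight decay 0.01) or RMSProp (lr 1e-3, momentum 0.9),
MSE task loss, transfer-loss weight λ = 0.1, batch 32.

Input conditioning: channels are autoscaled with statistics computed on the
labeled source data; the target pathway reuses the *source* statistics
interpolated onto its wavelength grid. Raw NIR channels are strictly
positive and strongly collinear, and the optimizer stalls without
centring. Using the target's own statistics would amount to an implicit
classical standardization of the slave — precisely the correction the
network is supposed to learn — so it is deliberately avoided.

Everything trains on a small in-package reverse-mode autodiff engine
(`nirshift.autodiff`) over numpy arrays; its gradients are checked against
central finite differences in the test suite.

## The five transfer losses

All five are scalar discrepancies between a source batch and a target
batch, added to the supervised loss as `MSE + λ·transfer`:

* **MK-MMD (DAN)** — biased V-statistic estimate of squared maximum mean
  discrepancy on the shared-layer features, averaged over a Gaussian
  bandwidth ladder (median heuristic × {¼, ½, 1, 2, 4}).
* **Weighted CDAN** — a discriminator on the outer-product conditioning
  `[g·f, g·(1−f)]` of features g and prediction f, with per-sample weights
  from a label histogram: the label range is cut into N = 10 equal
  segments, each segment's weight is `(p_k − p_min)/(p_max − p_min)`, so
  densely-populated label regions (where the spectra–label relation is
  best determined) drive the alignment. Source samples are weighted by
  their true labels, target samples by their predictions mapped back to
  label units. A flat histogram gives weight 1 everywhere (no information
  → nobody down-weighted); the emptiest segment gets weight 0 in the
  literal weighting function, while the *trainer* floors weights at 0.2 so
  the target term cannot silently vanish while early pseudo-labels are
  still rough.
* **MDD** — margin disparity adapted to regression: an auxiliary head f′
  mirrors the main head, the disparity is
  `mean_t[(f′−f)²] − γ·mean_s[(f′−f)²]` (γ = 4, tradeoff η = 1); f′
  ascends it, the features descend it.
* **ETD** — entropic optimal transport on the joint cost
  `‖g_i−g_j‖² + (f_i−f_j)²`, reweighted per pair by a small attention
  network (softplus scores normalized to mean 1), with a Kantorovich
  potential network acting as an adversarial critic regularizer
  (two-sided `mean_s g − mean_t g` through gradient reversal; the
  c-transform of the exact dual is not used).
* **GLOT** — a global entropic OT term between the feature clouds plus a
  local distributional-robustness term: the squared prediction change
  under the worst feature perturbation in an L2 ball (radius 0.1),
  approximated by one ascent step along the input gradient. The gradient
  direction is computed in a detached side graph (the engine has no
  higher-order differentiation); the surrogate is exact for a linear
  head, which the tests exploit as a closed-form oracle.

Sinkhorn iterations run in the log domain with uniform marginals
(rows 1/n_s, columns 1/n_t); ε defaults to 0.05 with 50 iterations inside
training and more in verification. The transport plan is treated as a
constant during backpropagation (envelope approximation); gradients flow
through the cost only.

## Stage-wise training

All stages are seeded and logged per iteration.

* **A — warm-up (400 iterations):** private-source + shared + head on
  source MSE.
* **Init:** the private-target layer starts as the private-source weights
  linearly interpolated onto the target grid, rescaled by a single
  data-driven factor so target pre-activations match the source scale.
  A per-unit moment-matched init was evaluated and rejected: it already
  performs most of the correction by construction, leaving nothing for
  the transfer losses to demonstrate.
* **B — private adaptation (200 iterations):** for the distribution
  losses (MK-MMD, ETD, GLOT) the private-target layer (plus any attention
  or critic networks) trains on the transfer loss alone, source-side
  layers frozen. For the min–max losses (CDAN, MDD) stage B instead
  pre-trains the adversary on frozen features — training the private
  layer purely adversarially, with no task anchor, mode-collapses. The
  second half of stage B refreshes shared + head on source batches.
* **C — joint fine-tune (500 iterations):** `MSE + λ·transfer` with a 0→1
  coefficient ramp on the adversarial parts. CDAN alternates a
  discriminator step (on detached features, standard two-sided form) with
  a non-saturating confusion step for the features; the saturating
  single-loss form measurably diverges. For CDAN and MDD the transfer
  gradient is routed to the private-target layer only, keeping the shared
  trunk anchored to the supervised task.

The iteration budget is part of the protocol: distribution alignment is
permutation-invariant, and training the alignment far beyond these budgets
slowly erodes the sample-wise pairing the resampled init provides (target
R degrades while the transfer loss keeps falling). The defaults are sized
for minutes-scale CPU runs and are freely overridable.

**Known limitation (CDAN).** Because distribution matching constrains only
the marginal of (f, g), a *mirror* solution — target predictions matching
the source distribution with reversed orientation (correlation ≈ −1) —
is a genuine attractor of the adversarial game at this scale, reached on
a minority of seeds. The mirror runs dominate variance in CDAN's cells of
the sweep experiments. MMD and OT losses, whose gradients refine the
already-oriented init much more coherently, do not show this failure.

## Classical baselines

DS solves `slave @ F ≈ master` by trace-scaled ridge least squares
(default 1e-8); PDS regresses each master channel on a ±w window of slave
channels matched by nearest wavelength (banded map, exact zeros outside
windows); SST takes the joint truncated SVD of the column-centered paired
standards `[M | S]` and reconstructs master spectra from slave factor
scores. DS and SST operate directly on the rectangular map between
different channel counts; transfer standards for fraction sweeps are the
first k samples of a seeded shuffle (reproducibility over optimal
selection; Kennard–Stone is out of scope).

## Synthetic benchmark

The generator renders Beer–Lambert-style additive Gaussian absorption
bands for three wood-like components (cellulose-, lignin- and
hemicellulose-like; 2–3 bands each between 950 and 1690 nm) on a dense
2048-point reference grid spanning 880–1720 nm. Labels (nominal tensile
strength) are a linear function of the component concentrations
(coefficients 50/40/30, concentrations uniform on [0.1, 1], label noise
sd 1.0, realized span ≈ 12–121). Each instrument applies Gaussian
response smoothing of a stated FWHM, a wavelength shift, gain/offset and a
linear baseline, samples onto its uniform grid and adds i.i.d. noise:

| profile | channels | FWHM (nm) | gain | offset | slope (1/nm) | shift (nm) | noise sd |
|---|---|---|---|---|---|---|---|
| master | 512 | 1.56 | 1.0 | 0 | 0 | 0 | 0.002 |
| slave  | 118 | 6.83 | 1.25 | 0.08 | 1.5e-4 | 2.0 | 0.004 |

Channel counts, span (900–1700 nm) and the two resolutions mirror the
two-instrument wood study; the distortion magnitudes are the package's own
choices of a plausible inter-vendor shift. Band positions and amplitudes
are synthetic, not calibrated wood optical constants.

What the generator does *not* emulate: per-sample multiplicative scatter,
instrument drift, wavelength-dependent noise, and — importantly — the
high intrinsic dimensionality of real wood spectra. With three latent
components the spectra have rank ≈ 3, so the classical DS/PDS/SST maps
saturate near R ≈ 99 with as little as 30 % of the transfer standards; on
real data their accuracy degrades sharply there. Passing benchmarks on
this generator therefore demonstrate correct mechanics and the
adaptation-over-baseline effect, not real-data effect sizes — and one
benchmark assertion (DS's R non-decreasing across transfer fractions) can
fail at that saturation ceiling, where DS's R moves by < 0.5 points
non-monotonically.

## Evaluation

R is the coefficient of determination in percent about the observed mean;
RMSE/RMSEP as usual; RMSECV pools squared errors over k = 10 seeded folds
(each fold's model retrained from scratch). The split-ratio sweep trains
each method on {25 … 70} % shares of the labeled source and scores target
R/RMSEP on held-out slave samples against generator truth, reported as
mean ± sd over reps. The transfer-fraction sweep fits each classical map
on {30, 50, 70} % of the paired standards and scores corrected slave test
spectra with one fixed ridge calibration model trained on the master
(keeping the scorer identical across fractions). Reported cells are
bit-reproducible given the dataset seed, the sweep seed and the config.

## Numerical choices and degenerate inputs

Linear interpolation (no extrapolation) for all grid resampling; CSV I/O
at 17 significant digits so round trips are lossless; `floor(ratio·n)`
training samples in splits; sigmoid discriminator outputs clamped to
[1e-6, 1−1e-6]; MMD clamped at 0 against roundoff; a flat label histogram
yields unit weights; empty spectra sets round-trip through CSV; Sinkhorn
runs in the log domain and tolerates ε down to 0.01 at the tested sizes.
A single global seed fans out to all components through
`numpy.random.SeedSequence`, which is what makes re-running a job from its
echoed configuration bit-identical.
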