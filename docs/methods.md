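# Methods

This note records the models, conventions, numerical choices, and
limitations behind `denoiseiq`, at the level of detail a maintainer needs
to interpret its outputs.

## Imaging and object models

A linear continuous-to-discrete imaging system `g = Hf + n` is simulated
with Gaussian point-response functions per detector (one detector per
pixel on the 0-based integer lattice):
`h_m(r) = A_m exp(-|r-r_m|²/(2 w_m²))`, `A_m = h/(2π w_m²)`. The object is
a lumpy random background plus, under the signal-present hypothesis, a
deterministic Gaussian signal (SKE/BKS). Because object components and
point responses are both isotropic Gaussians, the detector integrals have
closed forms; a component of amplitude `A`, width `w`, centered at `r₀`
contributes `A·h·w²/(w_m²+w²)·exp(-|r_m-r₀|²/(2(w_m²+w²)))` to pixel `m`.
The renderers evaluate only these closed forms (separably, via outer
products); the test suite validates them against 2-D quadrature of the
defining integral to better than 1e-3 relative error.

Lump counts are Poisson with mean `N̄`; lump centers are continuous-uniform
over `[0, rows) × [0, cols)`. Centers are not confined away from edges, so
ensemble-mean intensity decays near the borders; interior pixels have mean
`N̄·a·h·2π·w_b²/Area`.

**Noise.** Measurement noise is uncorrelated mixed Poisson–Gaussian:
`g_m = Poisson(max(b_m+s_m, 0)) + N(0, σ²)`, independently per pixel, with
the Poisson rate equal to the noise-free pixel value (non-integer rates
used directly). This convention analytically predicts a pooled
noisy-vs-noise-free RMSE of `sqrt(σ² + mean pixel intensity)` — about 75.4
for the 64×64 study — which the package reproduces, and which fixes the
convention among the several "mixed Poisson–Gaussian" variants in use.

**Study presets.**

| parameter | 32×32 study | 64×64 study |
|---|---|---|
| signal amplitude `A_s` / width `w_s` | 2.5 / 1 px | 3 / 2 px |
| signal center `r_s` | (16,16) | (32,32) |
| lumps `N̄`, `a`, `w_b` | 15, 5, 3 px | 50, 5, 3 px |
| collimator `h`, `w_m` | 20, 2 px | 20, 2 px |
| Gaussian noise σ | 25 | 75 |

Default ensemble sizes follow the standard protocol: 10,000+10,000
training pairs with noise-free targets, 200+200 validation pairs,
10,000+10,000 test images, 2,000+2,000 for observer calibration
(λ selection, CHO channel statistics), and up to 100,000+100,000
noise-free images for covariance estimation. Every split draws from an
independent child of a single seed sequence, so any split regenerates
byte-identically from `(config, seed)` without generating the others.

## Observers

* **HO**: `w = K_g⁻¹ Δḡ`, `K_g = (K₀+K₁)/2`. The solve refuses condition
  numbers above 1e12 and directs the caller to the RHO.
* **RHO**: eigendecomposition of the symmetric PSD `K_g` (equal to its
  SVD); singular values above `λ·σ_max` are retained and the template is
  the pseudo-inverse on that subspace applied to `Δḡ`. λ is selected by
  maximizing empirical AUC on a held-out calibration set over the
  decade grid {1e-3, …, 1e-7}; ties resolve toward the larger
  (more strongly regularized) λ. As λ → 0 the RHO reproduces the HO for
  invertible `K_g`.
* **CHO**: 10 difference-of-Gaussians frequency channels,
  `C_j(ρ) = exp(-ρ²/(2(Qσ_j)²)) - exp(-ρ²/(2σ_j²))`, `σ_j = σ₀·α^j`,
  j = 1…10, `σ₀ = 0.005` cycles/pixel, `α = 1.4`, `Q = 1.67`, built on the
  DFT frequency grid and phase-shifted so the spatial templates center on
  the known signal location. Rows are not normalized (scale cancels in
  the statistic). Internal noise `K_int = ε·diag(K_v)` with `ε = 2.5`
  enters both the template and, as a per-trial seeded Gaussian draw, the
  channel outputs. With identity channels and `ε = 0` the CHO reproduces
  HO decisions exactly.
* **NPWMF**: `w = Δḡ`; first-order statistics only, so denoising-induced
  covariance changes cannot affect it except through the mean.
* **CNN observer**: L conv layers (32 filters, 3×3, ReLU), global average
  pooling, one logistic unit; cross-entropy training (Adam 1e-4,
  class-balanced batches), model selection by validation AUC. Deep
  instances approximate the ideal observer; on white-noise Gaussian toys
  with a constant mean shift (where the ideal statistic is the pixel
  mean) the trained observer reaches the analytic `Φ(d/√2)` within test
  tolerance. The exact filter counts/head are this package's choice; no
  conclusion here depends on matching any particular published
  architecture detail.

Covariance estimation is either empirical (unbiased sample covariance per
class) or by decomposition, `K = K_background + diag(mean noise-free
image) + σ²I`, valid because the mixed noise is uncorrelated with
per-pixel variance equal to the Poisson rate plus σ². The two routes agree
within sampling error on simulated ensembles (tested by Monte Carlo).

## Denoising networks

All convolutions are 3×3, zero-padded "same" (the networks preserve image
size; padding is a package choice). Feature widths: 32 (linear family),
64 (nonlinear families).

* **linear**: D conv layers, no nonlinearities: 1→32, 32→32 ×(D−2), 32→1.
  The channel collapse sits at the final (Dth) layer so the feature width
  is constant through the first D−1 layers, which keeps the layerwise
  analysis uniform.
* **cnn**: Conv+ReLU, Conv+BN+ReLU ×(D−3), Conv+BN, Conv.
* **resnet**: the cnn layout plus identity skips around every consecutive
  pair of middle blocks and one long skip from the first block's output
  to the last layer's input; trained with the perceptual loss.

**Losses.** The MSE loss is the batch mean of per-image squared L2 norms.
The perceptual loss is the same quantity in the feature space of a frozen
extractor φ producing 64 maps at input resolution. The default φ is a
fixed-seed random two-layer conv bank (a synthetic stand-in with the same
geometry as the first block of a large pretrained classifier); any object
with the same forward/backward interface can be plugged in. Gradients
flow through φ to the denoiser but never update φ.

**Training protocol.** Adam (β₁=0.9, β₂=0.999, eps=1e-8) at learning rate
1e-4; each mini-batch contains equal numbers of signal-present and
signal-absent images drawn without replacement per step; the checkpoint
with the best validation loss is returned (early stop on patience).
Default budget is 200 epochs, patience 20; all budgets are config fields.
A low-noise-target variant (targets independently perturbed at a smaller
σ) exists as a config hook only.

**Standardization.** Inputs and targets are standardized by scalar
mean/std statistics of the training inputs; the inverse transform is
applied on output. This affine conjugation is part of the model: it folds
exactly into the first/last layer operators of the linear family and
leaves reported RMSE on the raw intensity scale. It is a numerical
necessity at this learning rate — raw intensities (~70±90) put the final
layer's weights orders of magnitude away from their initialization scale,
and Adam moves each coordinate at most ~1e-4 per step.

**Initialization** is Glorot-uniform everywhere (the engine's single
convention); BatchNorm uses momentum 0.9 and eps 1e-5, with running
statistics at inference so that denoising is deterministic.

**Engine.** Networks run on a purpose-built numpy engine: im2col + BLAS
matmul convolutions (channels-last float32), hand-derived backward passes
(input gradients computed as a convolution with the rotated,
channel-transposed kernel — no scatter-adds), verified against
scipy.signal and central finite differences. Training is bit-reproducible
from the seed in a fixed BLAS environment; across BLAS builds,
reproducibility holds to floating-point tolerance.

## Covariance propagation and the layerwise RHO

Each linear-family layer is materialized as a sparse matrix (≤ 9·C_in
nonzeros per row) plus a bias vector, with feature tensors vectorized
channels-fastest; the standardization constants fold into the first and
last operators, so the operator chain applied to a raw vectorized image
reproduces `denoise()` to ≤1e-5 relative error (tested).

Mean differences propagate as `Δ_d = W_d…W₁ Δ₀` (biases cancel);
covariances as `K_d = W_d…W₁ K₀ W₁ᵀ…W_dᵀ`. At 32×32 with 32 channels,
`K_d` is 32768² and is never formed densely: the package propagates the
square-root factor `B_d = W_d…W₁ K₀^{1/2}` (32768×1024) and works with
the Gram matrix `G = B_dᵀB_d`, whose eigenvalues are exactly the singular
values of `K_d`. RHO templates at layer d are
`w_d = B_d V_r diag(s_r⁻²) V_rᵀ B_dᵀ Δ_d`; since layer outputs are affine
in the input and biases cancel in ROC analysis, templates are pulled back
to image space (`w_img = W₁ᵀ…W_dᵀ w_d`) and applied directly to raw
images, avoiding any materialization of feature ensembles. The dense
path (small grids) is the contract check for the factored one; both are
validated against Monte-Carlo statistics of propagated samples. λ
selection at every layer uses the same sweep protocol as in image space.

The final linear layer (32 channels → 1) has a wide operator matrix with
rank at most the pixel count, hence a nontrivial null space: task-relevant
covariance structure can be annihilated there, which is the mechanism the
layerwise table quantifies.

## Evaluation methodology

Empirical AUC is the Mann–Whitney statistic (ties counted ½) — exact
pair-set equivalence is property-tested against brute-force counting.
Standard errors use the Hanley–McNeil closed form (bootstrap available as
a cross-check); at AUC ≈ 0.64 with 10,000 images per class this gives
≈ 0.0039. A Gaussian-moment binormal AUC is provided as an optional
cross-check; empirical AUC is canonical throughout. "Significant" means
non-overlap of ±2·SE bands; no multiple-comparison correction is applied.

Detection efficiency is `e = AUC_denoised / AUC_noisy` for the same
observer; it can exceed 1 for sub-optimal observers, while for an ideal
observer the data-processing inequality bounds it at 1 (checked as a soft
assertion against sampling error).

RMSE is pooled over all pixels of all images. SSIM uses the standard
formulation (11×11 Gaussian window, σ=1.5, K₁=0.01, K₂=0.03) with the
data range set to the max−min of the noise-free target ensemble. SSIM
values depend materially on this dialect, so it is an explicit argument
and a recorded choice. Under heavy noise the choice of window scale
dominates: the default 1.5-pixel Gaussian window sees an almost-smooth
target locally, so the structure term — and hence the mean SSIM of noisy
images (≈0.13 for the 64×64 study) — is several times smaller than what
a window wide enough to span whole lumps (σ≈6 px, ≈0.37) would report.
Published SSIM values are not comparable across dialects.

## Desk-scale budgets

The acceptance script and test suite run the full pipelines at reduced
problem sizes chosen once for single-CPU execution:

* Noisy-image RHO (32×32): decomposition covariance from 20,000 noise-free
  images per class; λ selected on 2,000+2,000; AUC on 10,000+10,000 test
  images (full protocol sizes).
* Depth-9 linear denoiser: 2,000+2,000 training pairs, mini-batches 25+25,
  100 Adam steps, best-validation checkpoint (the layerwise AUC pattern is
  insensitive to the linear-family training budget beyond ~50 steps).
* 64×64 noisy metrics: RMSE over 5,000+5,000 images; SSIM over
  1,000+1,000.
* Depth-3 CNN denoiser: 2,000+2,000 training pairs, mini-batches 8+8,
  850 Adam steps in the acceptance script (300 in the test suite), with
  checkpoint selection on a 50+50 validation subset; RMSE on 1,000+1,000
  held-out test images. The depth trend (deeper no worse) is checked at a
  matched 250-step budget per depth.

Mini-batch sizes are scaled down with the ensembles: at learning rate
1e-4 Adam's progress is step-count-bound rather than batch-size-bound, so
smaller class-balanced batches reach the same loss sooner in wall-clock
time; batch-norm statistics remain well-estimated because they pool over
all pixels of the batch.

## What the synthetic data does and does not show

The generator emulates planar scintigraphy at the level of an idealized
linear collimator with stationary Gaussian optics, Gaussian lumps, and
pixelwise mixed noise. It deliberately omits scatter, attenuation,
depth-dependent blur, detector nonuniformity, anatomical backgrounds, and
signal variability. Passing tests therefore demonstrate the internal
consistency of the estimators and the denoising-versus-detection
phenomenology under the stated model — not performance on clinical data.
Conclusions about specific published architectures are likewise outside
scope: the nonlinear networks follow the stated layer recipes, but
training budgets here are desk-scale.

## Known limitations

* The ideal-observer surrogate (CNN observer) is validated only on toys
  with a known ideal statistic; on lumpy backgrounds its absolute AUC is
  a lower bound on the IO's.
* Covariance propagation applies to the linear family only; nonlinear
  networks are evaluated empirically.
* The ResNet/perceptual path uses the synthetic feature bank by default;
  results with a pretrained extractor may differ.
* Empirical AUC differs from a proper-binormal ROC fit by well under one
  standard error at these sample sizes, but fitted-curve quantities
  (e.g., TPF at fixed FPF) are not implemented.
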