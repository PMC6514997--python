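# Methods

## Problem setting

MRI acquires samples of the 2D spatial-frequency transform (k-space) of the
object.  Scan time is proportional to the number of phase-encode samples, so
accelerated imaging records only a subset ℧ of the k-space grid.  `sifomri`
reconstructs a 2D image x ∈ ℂ^q from such undersampled measurements

    z = F_u x + noise,

where F_u is the centered *unitary* 2D DFT restricted to ℧.  Filling the
unmeasured cells with zeros and inverting (the "zero-filled" image) leaves
structured aliasing; the reconstruction removes it by requiring every small
image patch to be sparse in a dictionary learned from the image itself.

## Model

All overlapping √n×√n patches R_ij x (stride r, default n = 36, r = 1) are
approximated as R_ij x ≈ D θ_ij with a dictionary D ∈ R^{n×K} of unit-norm
atoms (default K = 36) and codes with at most τ0 nonzeros (default 6).  The
joint objective is

    min_{D, {θ_ij}, x}  Σ_ij ‖R_ij x − D θ_ij‖²  +  η ‖F_u x − z‖²
                        s.t. ‖θ_ij‖₀ ≤ τ0,  ‖d_k‖₂ = 1,

with η = λσ (λ = 140) tying data fidelity to the k-space noise level σ.
It is minimized by alternating three steps per outer iteration (default 15):

1. **Dictionary learning** on a random subset of 200·K patches of the current
   estimate (fresh subset every iteration; the dictionary warm-starts from the
   previous iteration, and from raw patches at the first).
2. **Sparse coding** of *all* patches against the learned dictionary.
3. **Data consistency**: the patch approximations are averaged pixel-wise into
   an image ("patched average"; each pixel divided by its exact coverage
   count, so borders are averaged correctly), and its spectrum N is corrected
   at the measured cells: N ← N0 exactly when σ = 0, or the convex blend
   (N + η N0)/(1 + η) when σ > 0, where N0 is the zero-filled measurement.

Two method arms share this loop:

* **SiFo** — regularized SimCO dictionary updates + FOCUSS sparse coding;
* **DLMRI baseline** — K-SVD dictionary updates + OMP sparse coding.

### FOCUSS

FOCUSS solves min ‖b‖² s.t. D M b = x with a diagonal weighting
M = diag(|θ|^p) (default p = 0.5) that is re-derived from the current iterate:

    M_l = diag(|θ_{l−1}|^p),
    b_l = argmin ‖x − D M_l b‖² + λ_r ‖b‖²,
    θ_l = M_l b_l,

for 8 inner iterations, with λ_r = 10⁻⁶‖x‖² stabilizing the pseudo-inverse.
Coefficients below 10⁻⁴·max|θ| are pruned to zero and stay zero (this pruning
is what suppresses incoherent aliasing/noise — the "soft" sparsity).  After
the last iteration the code is hard-thresholded to the τ0 largest magnitudes
and re-fit by least squares on that support, so the ℓ0 bound always holds.
Initialization is the matched filter θ0 = Dᵀx.  A per-iteration ridge floor
10⁻¹⁰·max(w²) guards the solve for numerically dead columns (the weights
|θ|^{2p} and the ridge ‖x‖² scale differently when p ≠ 1); it is inactive for
any column with meaningful content.  The many-column path solves the n×n
weighted normal equations batched, switching to the s×s dual (Woodbury) form
when the weight support has ≤ max(τ0+2, n/3) entries; it matches the
per-column reference to solver precision.

### SimCO

The dictionary update minimizes f(D) = Σ_j ‖x_j − Dθ_j‖² + μ‖θ_j‖²
(μ = 0.05) over the product of unit spheres, holding each column's sparsity
*pattern* fixed while re-optimizing its values: for any candidate D the codes
are the ridge least-squares coefficients on their support, the Euclidean
gradient −2(X − DΘ)Θᵀ is projected onto each atom's tangent space, and a
backtracking Armijo line search (initial step 1, shrink 0.5, sufficient
decrease 10⁻⁴) with renormalization retraction takes 5 steps per call.  The
objective never increases; atoms used by no patch have zero gradient and stay
fixed (logged).  Armijo backtracking replaces the golden-section search of
the original SimCO description — simpler, with the same monotonicity.

### K-SVD / OMP baseline

Standard K-SVD: per atom, the restricted residual over the patches using it
is replaced by its best rank-1 approximation (leading singular pair); unused
atoms are reseeded with the worst-represented patch.  OMP greedily selects
the maximally correlated atom and re-solves least squares on the growing
support until τ0 atoms or a negligible residual.

### Patch DC handling

Patches are coded zero-mean: the per-patch mean is removed before training
and coding and added back to the approximation.  The dictionary then spends
its atoms (and the τ0 budget) on structure rather than brightness level; flat
patches cost nothing.  On the 128×128 ten-fold phantom benchmark this raises
the SiFo improvement over zero-filling from ≈2 dB to ≈3.6 dB in 10
iterations.  Raw (mean-preserved) coding is available via
`ReconConfig(center_patches=False)`.

The estimate is kept complex throughout; patches are coded on the real part
(real-valued sparsifying transform, appropriate for magnitude images), with
`complex_patches=True` switching to magnitude coding.

## Sampling masks

* `vd_random` — variable-density random: cell probability ∝ (1 − r̂)³ in
  normalized k-space radius r̂, with a fully sampled central disc of radius
  min(shape)/32; the exact budget ⌊q/fold⌋ is drawn without replacement.  The
  density law and center size are package choices (the scheme's literature
  states no canonical profile).
* `cartesian` — full phase-encode rows: ⌊rows/fold⌋ rows, a contiguous
  central block always included, the rest drawn with the same variable
  density over row distance.
* `radial` — equally spaced straight spokes through the center, rasterized to
  the nearest grid cell; the spoke count is the smallest achieving the
  requested fold within 10%.

The DFT is unitary with DC centered, so Parseval holds exactly and a noise σ
expressed in k-space units is comparable across grid sizes.  Measurement
noise is i.i.d. Gaussian, σ per real/imaginary component, added at sampled
cells only.

## Metrics

* **PSNR** = 20 log₁₀(peak/RMSE), peak = reference maximum, on magnitudes.
* **HFEN** = ‖LoG(recon − ref)‖₂ / ‖LoG(ref)‖₂ with the 15×15, σ = 1.5
  Laplacian-of-Gaussian kernel conventional in this literature; the
  normalization makes values scale-free.  Symmetric boundary padding.
* **SSIM** — mean structural similarity, 11×11 Gaussian window σ = 1.5,
  constants (0.01 L)², (0.03 L)², L = reference dynamic range
  (scikit-image implementation).
* **Correlation** — Pearson correlation over all magnitude pixels.
* **Sharpness** — Tenengrad (mean squared Sobel gradient magnitude): an
  edge-energy score of a single image, included for completeness; it is not a
  fidelity measure and has no canonical definition in this literature, so no
  quantitative claims are attached to it.

## Synthetic data

`shepp_logan(size)` rasterizes the canonical 10-ellipse head phantom at any
grid size (high-contrast intensity variant by default; the low-contrast
original is scaled by its table maximum 2.0).  Note the canonical phantom is
*not* left-right intensity-symmetric: the two large dark ellipses differ in
size, and the small bottom ellipses are offset; only the head outline is
mirror-symmetric.  `brain_like(size, seed, ...)` draws a seeded
piecewise-smooth surrogate for a T2-weighted brain slice — an elliptical
skull, random-intensity interior blobs, low-pass texture.  It reproduces the
piecewise-smooth, sharp-edged character of brain images but none of their
anatomy, coil shading, or partial-volume effects, so tests passing on it
demonstrate algorithmic behavior, not clinical performance.
`planted_sparse_instance` builds exact sparse ground truth (unit-norm random
dictionary, ±Uniform(0.5, 1.5) coefficients) for coder/learner oracles.

## Problem sizes used in the test suite

The full experimental protocol (512×512 images, stride 1, 15 iterations) is
hours of single-core work, so the automated suite runs the same pipeline at
reduced scale, chosen once:

* improvement benchmark: 128×128 phantom, 10-fold variable density,
  noiseless, stride 1, 10 iterations;
* paired noisy comparison: 128×128 phantom, 4-fold Cartesian, σ = 10.2489,
  stride 3, 6 iterations, 10 mask/noise seeds;
* quantitative phantom check: 512×512 phantom, 10-fold variable density,
  stride 4, 15 iterations, noiseless and σ = 10.2489.

Because the original masks and density profile are unspecified, quantitative
comparisons against published phantom correlation/SSIM values are stochastic
checks at reduced scale, not exact reproductions.

## Numerical choices and degenerate inputs

* Exactly-zero patch columns get exactly-zero codes; after centering, flat
  patches reduce to roundoff dust and are zeroed explicitly.
* Batched small linear systems carry a 10⁻¹² jitter against exact rank
  deficiency; support refits use least squares.
* σ = 0 with `weighted` data consistency would make η = λσ = 0 and discard
  the measurements; the loop falls back to exact restoration and warns.
* Dictionary sign/permutation ambiguity is accepted; all comparisons are via
  representation error, never atom identity.
* Determinism: every random choice (masks, noise, training subsets,
  dictionary init) flows from explicit integer seeds; a full run is
  bit-reproducible on one platform.

## Known limitations

* Single-coil, Cartesian-grid model only; no NUFFT, no parallel imaging, no
  3D or dynamic data.
* K = n = 36 (complete, not overcomplete) follows the experimental protocol;
  edge-rich patches are the fit bottleneck at this capacity.
* FOCUSS convergence is slow on patches with broad correlation spectra; the
  inner iteration count trades speed for code concentration.
* η = λσ is implemented as specified for the weighted mode; with λ = 140 and
  σ ≈ 10 the blend is strongly measurement-dominated, so k-space denoising is
  mild and most noise removal comes from the patch model.
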