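# sifomri

Compressed-sensing MRI reconstruction from undersampled k-space via
patch-based adaptive dictionary learning.

MRI scan time scales with the number of k-space samples acquired, so
accelerated protocols measure only a fraction of the grid (`z = F_u x`), and
naive zero-filled inversion leaves heavy aliasing.  This package removes that
aliasing by learning a sparsifying dictionary from the image's own patches
while reconstructing, alternating two stages:

1. **Dictionary learning + sparse coding** of all overlapping √n×√n patches
   of the current estimate, minimizing

       Σ_ij ‖R_ij x − D θ_ij‖²  +  η ‖F_u x − z‖²,
       s.t. ‖θ_ij‖₀ ≤ τ₀,  ‖d_k‖₂ = 1,

2. **k-space data consistency**: the patch approximations are averaged into
   an image whose spectrum is corrected at the measured cells — replaced
   exactly when noiseless, or blended as (N + ηN₀)/(1 + η) with η = λσ when
   noisy.

Two interchangeable arms are provided:

* **SiFo** — *regularized SimCO* dictionary updates (all atoms moved
  simultaneously on the product of unit spheres, sparsity pattern fixed) with
  *FOCUSS* sparse coding (iteratively reweighted minimum norm, a soft
  sparsity constraint whose pruning suppresses incoherent aliasing);
* **DLMRI baseline** — K-SVD dictionary updates with OMP coding, the classic
  comparison arm.

It also ships the sampling-mask generators (variable-density random,
Cartesian lines, pseudo-radial spokes), the evaluation metrics used in this
literature (PSNR, normalized HFEN, SSIM, correlation, Tenengrad sharpness),
and seeded synthetic fixtures (Shepp-Logan phantom at any size, brain-like
piecewise-smooth images, planted sparse-coding instances).  It is aimed at
researchers benchmarking sparse-recovery MRI methods; everything is seeded
and bit-reproducible.

## Worked example

```python
import sifomri as sm

truth = sm.shepp_logan(128)                                   # [0, 255] phantom
mask = sm.make_vd_random_mask((128, 128), fold=10, seed=0)    # 10% of k-space
meas = sm.undersample(truth, mask, noise_sigma=0.0, seed=0)

zf = sm.zero_filled_recon(meas)
print(f"zero-filled PSNR: {sm.psnr(zf.pixels, truth.pixels):.2f} dB")

cfg = sm.ReconConfig(outer_iters=10, seed=0)                  # tau0=6, n=K=36, ...
res = sm.sifo_reconstruct(meas, cfg, reference=truth)
final = res.image.pixels
print(f"SiFo PSNR: {sm.psnr(final, truth.pixels):.2f} dB, "
      f"HFEN: {sm.hfen(final, truth.pixels):.3f}, "
      f"SSIM: {sm.ssim(final, truth.pixels):.3f}")
```

Output:

```
zero-filled PSNR: 17.87 dB
SiFo PSNR: 21.48 dB, HFEN: 0.307, SSIM: 0.437
```

The ten-fold undersampled phantom gains ≈3.6 dB over the zero-filled
baseline in ten iterations: the learned dictionary reconstructs the phantom's
edges while the data-consistency step keeps the estimate pinned to the
measured k-space cells.  HFEN (high-frequency error norm, lower is better)
measures how well edges and fine features are restored; `res.per_iteration`
holds the (PSNR, HFEN, objective) trajectory.

The same pipeline is scriptable from the shell:

```sh
sifomri phantom --size 128 --out truth
sifomri recon --input truth.npy --mask vdrandom --fold 10 --method both \
              --iters 10 --seed 0 --out-dir run/
sifomri metrics --a run/recon_sifo.npy --b run/reference.npy --out report.csv
```

`sifomri recon` writes the reconstructions (PNG + lossless `.npy`), the mask,
per-iteration metric CSVs, and a JSON manifest from which the run can be
repeated bit-exactly (`sifomri run run/manifest.json`).

## Layout

| module | contents |
| --- | --- |
| `sifomri.gridops` | unitary centered FFT pair, sampling masks, measurement model |
| `sifomri.patchops` | overlapping patch extraction / patch-average reassembly |
| `sifomri.sparse_coding` | FOCUSS and OMP coders (per-column + batched paths) |
| `sifomri.dict_learning` | SimCO, K-SVD, initialization, alternation driver |
| `sifomri.recon` | data-consistency update and the SiFo / DLMRI outer loops |
| `sifomri.metrics` | PSNR, HFEN, SSIM, correlation, sharpness |
| `sifomri.fixtures` | Shepp-Logan, brain-like images, planted sparse instances |
| `sifomri.cli`, `sifomri.imgio` | command line, config/manifest, image I/O |
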