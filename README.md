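# ecmri — error-corrected compressed-sensing MRI reconstruction

`ecmri` is a toolkit for studying residual error correction in
compressed-sensing MRI (CS-MRI).  It is aimed at imaging-methods
researchers who want a fully reproducible, CPU-scale testbed for the
guide / error-correction / data-fidelity decomposition, with every
stage — acquisition simulation, sampling-mask generation, iterative
sparse solvers, network training, and quality metrics — exercisable on
synthetic complex-valued phantoms (no clinical data required).

## The method

CS-MRI acquires a fraction of k-space, `y = F_u x`, and solves

    x̂ = argmin_x ‖F_u x − y‖² + Σ_i α_i Ψ_i(x)

Any such solver ("guide") leaves structured residual errors.  The
framework here refines a guide reconstruction `x̄ = invMRI(y)` in two
steps:

1. a residual CNN `f_θ` receives the **concatenation** of the
   zero-filled image `Z(y) = F_uᴴy` and the guide `x̄` (real/imaginary
   parts as four channels) and is trained to predict the error
   `Δx = x_true − x̄` by minimizing `½‖Δx − f_θ(Z(y), x̄)‖²`;
2. the corrected image `x̄ + f_θ(Z(y), x̄)` is fused with the
   measurements by the closed-form k-space solve of
   `argmin_x ‖F_u x − y‖² + α‖x − (x̄ + f_θ)‖²`, which is pointwise:
   sampled coefficients become `(y + α s)/(1 + α)`, unsampled keep
   `s = F(x̄ + f_θ)`; default `α = 5·10⁻⁵`.

Built-in guides: zero-filled, an ISTA solver of the sparse objective
(orthonormal wavelet or total-variation regularizer), a trainable
deep-cascade CNN, and file-based import of externally computed guide
images.  See `docs/methods.md` for conventions, parameters and
limitations.

## Worked example

```python
from ecmri import (PhantomConfig, make_phantom, make_cartesian_mask,
                   undersample, zero_fill, psnr, ssim, fidelity_correct)
from ecmri.guides import IterativeSparseGuide, SparseSolverConfig

truth = make_phantom(PhantomConfig(size=(64, 64), seed=42))
mask = make_cartesian_mask(64, 64, ratio=0.30, seed=7)   # 30% of rows
y = undersample(truth, mask)

zf = zero_fill(y)
guide = IterativeSparseGuide(
    SparseSolverConfig(transform="tv", reg_weight=2e-3, max_iters=80)).reconstruct(y)
corrected = fidelity_correct(guide, y, 5e-5)

for name, img in [("zero-filled", zf), ("TV guide", guide), ("guide+fidelity", corrected)]:
    print(f"{name:>15}: PSNR {psnr(truth, img):6.2f} dB   SSIM {ssim(truth, img):.4f}")
```

prints

```
    zero-filled: PSNR  29.10 dB   SSIM 0.8251
       TV guide: PSNR  32.69 dB   SSIM 0.9409
 guide+fidelity: PSNR  32.72 dB   SSIM 0.9405
```

The zero-filled reconstruction is aliased (29.1 dB); the TV guide
removes most aliasing (+3.6 dB); the data-fidelity solve then snaps
the sampled k-space coefficients back toward the measurements.
Training the error-correction network on top of the guide
(`ecmri.train_ec`, or the `ecmri train-ec` CLI command) adds a further
gain — +1.5 to +1.8 dB on the shipped desk-scale configuration,
depending on the seed — by restoring detail the guide smoothed away.

The same workflow is available from the shell:

```bash
ecmri simulate --n 100 --size 64 --seed 0 --out data/
ecmri train-ec --dataset data/ --mask-ratio 0.30 --guide sparse_tv --out ckpt
ecmri evaluate --dataset data/ --mask-ratio 0.30 --guide sparse_tv \
               --checkpoint ckpt --out metrics.csv
ecmri ablate   --dataset data/ --guide sparse_tv --out ablation.csv
```

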