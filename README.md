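# pcct — dual-domain photon-counting CT data correction

Photon-counting detectors (PCDs) classify individual x-ray photons into
energy bins by comparing pulse heights against a ladder of thresholds. Two
detector physics effects corrupt the measured spectrum: **charge splitting**
(a photon's charge cloud spreads across pixel boundaries and is recorded at
lower energies, possibly in neighboring pixels) and **pulse pileup** (photons
arriving within the dead time merge into one count with a distorted energy).
Together with Poisson noise these effects bias the counts-in-bins sinograms
and propagate into every reconstructed energy channel, where photon
starvation adds severe quantum noise.

`pcct` is a desk-scale toolkit for studying and correcting these
distortions. It is aimed at researchers in spectral CT algorithm development
who need a fully controlled simulation and correction chain that runs on a
single CPU:

1. **Simulation** — random multi-material ellipsoid phantoms (soft tissue,
   adipose, gray/white matter, blood, cortical bone in a water sphere),
   polychromatic parallel-beam forward projection, a parametric four-branch
   CdTe response (free penetration / full detection / fluorescence escape /
   fluorescence reabsorption), 4-neighbor cross-talk, Poisson noise, a
   paralyzable pileup model (event-level Monte Carlo or the first-order
   recorded-rate law m = n·e^(−nτ)), and threshold binning
   (20, 30, …, 110 keV → 9 bins).
2. **Projection-domain correction** — a residual Wasserstein GAN with
   gradient penalty. The critic loss is

   L_D = −E[D(p)] + E[D(G(m))] + λ_gp · E[(‖∇_p̂ D(p̂)‖₂ − 1)²],

   with p̂ sampled uniformly on the segment between the ideal patch p and the
   generated patch G(m). The generator minimizes

   L_G = −E[D(G(m))] + λ₁·E‖G(m) − p‖² + λ₂·E|(G(m) − p)/(p + ε)|
         + λ₃·‖ViT(G(m)) − ViT(p)‖²,

   where the perceptual term is the mean squared distance between the last
   hidden states of a small vision transformer (λ₁ = λ₂ = 1000, λ₃ = 10,
   ε = 10⁻⁴, Adam α = 10⁻⁴, β₁ = 0.9, β₂ = 0.999). The generator is fully
   convolutional with a global residual (output = features + input), so it
   trains on 16×16×9 patches and corrects whole projections in one shot.
   Everything runs on a small numpy reverse-mode autodiff engine
   (`pcct.nn`) with second-order support for the gradient penalty.
3. **Reconstruction** — per-bin filtered backprojection (ramp/Hann) and
   SART for parallel-beam geometry, after air correction
   p = −ln(counts/air).
4. **Image-domain denoising** — primal–dual TV (TV-L1 by default, λ = 1.0,
   18 iterations) followed by guided filtering (radius 5, ε = 10⁻⁸, applied
   1000 times) against a **virtual integrating bin**: the sum of pre-log
   counts over all energy bins, reconstructed and TV-denoised into a
   low-noise guidance image.
5. **Metrics** — RMSE (projection domain), PSNR/SSIM (image domain), noise
   power spectrum with a Parseval-consistent normalization, and one-way
   ANOVA for method comparisons.

## Worked example

```python
from pcct.fixtures import make_fixture
from pcct.gan import (NetConfig, LossWeights, TrainState, ViT,
                      extract_patch_pairs, split_train_val, train_wgan)
from pcct.pipeline import run_dual_domain_chain

# 64^3 phantom, 60 views, 9 energy bins, all distortions on
ds = make_fixture("small", seed=7)
pairs = extract_patch_pairs(ds.distorted, ds.ideal, 2000, seed=11)
train_set, val_set = split_train_val(pairs, 0.95)

cfg = NetConfig.compact(n_bins=9)      # CPU-scale widths
gen, hist = train_wgan(train_set, val_set, cfg, LossWeights(),
                       TrainState(epochs=5, batch_size=64, critic_steps=2, seed=3),
                       vit=ViT(cfg))
print(hist["val_rmse"])

res = run_dual_domain_chain(ds, gen)
print(res.ssim_noisy.round(3))
print(res.ssim_denoised.round(3))
```

A representative run prints a validation RMSE trajectory of

```
[0.00821, 0.00447, 0.00349, 0.00278, 0.00232]
```

against an uncorrected (identity) baseline of 0.02157 — the network removes
most of the systematic count loss and spectral shift within five epochs.
The per-bin SSIM of the reconstructions against the noise-free ground truth
then improves from

```
noisy:    [0.798 0.765 0.618 0.477 0.368 0.312 0.255 0.189 0.140]
denoised: [0.826 0.889 0.858 0.823 0.793 0.767 0.748 0.735 0.723]
```

— the high-energy bins, which suffer most from photon starvation, gain the
most from the dual-domain chain.

The same pipeline is scriptable from the shell:

```bash
pcct fixture --scale small --seed 7 --out data/
pcct train --distorted data/distorted.h5 --ideal data/ideal.h5 \
     --checkpoint gen.npz --n-patches 2000 --epochs 5
pcct correct --checkpoint gen.npz --distorted data/distorted.h5 --out corrected.h5
pcct reconstruct --sinogram corrected.h5 --air data/air_ideal.npy --out recon.h5
pcct reconstruct --sinogram data/ideal.h5 --air data/air_ideal.npy --out gt.h5
pcct denoise --recon recon.h5 --prelog data/distorted.h5 \
     --air data/air_distorted.npy --out denoised.h5
pcct evaluate --result denoised.h5 --reference gt.h5
```

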