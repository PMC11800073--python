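# Methods

This note records the models, parameter choices and numerical decisions
behind `pcct`, and what the synthetic experiments do and do not demonstrate.

## Phantoms and attenuation data

Phantoms are cubes of voxels carrying a weight vector over an ordered
material list. Five ellipsoids (materials drawn without replacement from
soft tissue, adipose, gray matter, white matter, blood, cortical bone) are
placed fully inside a containment sphere; overlapping voxels become an
equal-weight mixture of the involved materials, gaps are water, the exterior
is air. Because no sampling law for "random shapes" is canonical, we sample
ellipsoid centers uniformly in the sphere shrunk by the largest semiaxis,
semiaxes uniformly in [0.1R, 0.5R], and orientations uniformly over
rotations; this guarantees containment by construction. The full-scale
defaults are a 256³ grid of 0.11 mm voxels with a 12.8 mm sphere.

The packaged attenuation tables are **synthetic**: a two-term model
(photoelectric ∝ E⁻³ plus a Klein–Nishina-shaped Compton term) least-squares
fitted to approximate anchor values of μ/ρ at 30/60/100 keV per material, on
a 1 keV grid from 10 to 150 keV. The source spectrum is Kramers-law
bremsstrahlung at 120 kVp filtered by 0.8 mm Be / 1.0 mm Al / 0.11 mm Cu on
a 12–120 keV grid (109 channels). Both are plain-text inputs and can be
replaced by measured tables; K-edges and characteristic lines inside the
imaging range are not modeled. Linear attenuation interpolates the tables
log-log and refuses to extrapolate.

## Forward projection

Parallel-beam line integrals use Joseph-style interpolated sampling with a
step of half a voxel. Since μ_voxel(E) = Σ_k w_k μ_k(E), the projector
integrates each material's weight field once and recombines with μ_k(E),
making the 109-channel spectral sinogram essentially free after K ray
marches. Expected ideal counts are λ = N₀ w(E) exp(−L(E)) with N₀ = 400 000
photons per pixel per view. Detector rows map one-to-one onto phantom
z-slices; rotational anisotropy of the bilinear interpolation is ~2–3% of
the path length (tested). The default detector covers the phantom diagonal:
columns are the next multiple of 16 above √2 × grid size at one voxel pitch.

## Detector model

The spectral response R[E_rec, E_in] combines four single-interaction
branches: free penetration (lost), full detection at E_in, fluorescence
escape recorded at E_in − E_fluor (mean Cd/Te Kα, 25.35 keV), and
fluorescence reabsorption at E_in, each blurred by a Gaussian energy
resolution (σ = 2 keV). Branch probabilities are parametric and
configurable: penetration rises smoothly from 1% to ~31% across 12–120 keV,
and above the Cd K-edge 15%/25% of detected photons excite fluorescence
that escapes/reabsorbs. Column sums equal 1 − P(penetration) except where
escape mass falls below the grid floor (it is then unrecorded). An
externally computed response matrix can be loaded instead; the pipeline
does not depend on these particular numbers.

Cross-talk moves a fixed fraction (default 0.1) of each pixel's recorded
counts equally onto its 4 neighbors; shares that would leave the detector
edge stay in place so total counts are conserved exactly.

The chain order is fixed: response/cross-talk → Poisson → pileup → binning.
Pileup is paralyzable. The event-level mode draws uniform arrival times over
the exposure, registers an event only when it follows its predecessor by
more than the dead time τ, and sums merged energies with exponential tail
weights exp(−Δt/τ) from the cluster start — a surrogate for the bipolar
pulse shape, swappable in code. The analytic mode applies the first-order
recorded-rate law m = n e^(−nτ) per pixel and moves the piled fraction
α = 1 − e^(−nτ) onto the self-convolution of the pixel's spectrum (overflow
folded into the top channel); it is the default for full sinograms, where
event-level simulation at 400k counts/pixel is impractical. The default
dead time (125 ps at a 1 ms exposure) puts the flux at nτ ≈ 0.05 — mild
pileup, ~5% count loss. Thresholds default to 20, 30, …, 110 keV; bins are
adjacent differences of counts-above-threshold, so 10 levels give 9 bins
and counts above the top level are discarded.

## Correction network

The generator is a fully convolutional contract–expand network (two
encoding convolutions, one stride-2 downsampling, two middle convolutions,
transposed-convolution upsampling, one skip concatenation, fusion, and a
zero-initialized head) with a global residual add, so the freshly built
network is exactly the identity and inference runs on whole projections
with no patch stitching. The critic is the residual design: a 3×3
convolution to the initial width, four stride-2 residual blocks (two 3×3
convolutions with batch normalization, 1×1 strided shortcut, ReLU after the
add), flatten, dense + leaky ReLU, dense → one unsquashed score. Full-scale
widths (64/128/256/512, dense 1024) are the `NetConfig()` defaults;
`NetConfig.compact()` and the still smaller smoke configuration used by the
test suite shrink every width so adversarial training fits a single CPU.
Desk-scale training (2000 pairs, 5 epochs, batch 64, 2 critic steps per
generator step) runs in ~2 minutes per seed and reliably cuts validation
RMSE by roughly 10× against the distorted baseline; the full-scale
regime (1.8M pairs, 40 epochs, 4 critic steps) is the configured default
but is a GPU-scale undertaking not exercised here.

The WGAN-GP adversarial convention is the standard one: the critic
minimizes −E[D(p)] + E[D(G(m))] + λ_gp·penalty (λ_gp = 10, one uniform
interpolate per pair), the generator minimizes −E[D(G(m))]; a config flag
flips the generator sign for experimentation. The gradient-norm penalty
uses √(Σg² + 1e−12) during training for a finite derivative at zero; the
loss functions themselves default to the exact norm. Patch values are
counts divided by N₀ = 400 000, stored with checkpoints.

The perceptual feature is the last hidden state (all token embeddings) of a
small ViT: non-overlapping 4×4 tokenization over all bins, linear
projection, learned positional embeddings, pre-norm transformer blocks, an
optional class token (off by default). The perceptual distance is the mean
squared feature difference. The transformer can be pre-trained as a
distorted→ideal patch regressor through a discarded linear decoder
(`pretrain_vit`); the frozen random-init encoder is the default in the smoke
experiments — at these scales the pixel-space losses dominate and the random
frozen features already provide a stable perceptual metric.

Everything trains on `pcct.nn`, a reverse-mode autodiff engine over numpy
whose vector-Jacobian products are expressed in its own primitives, so the
second-order pass needed by the gradient penalty (gradient of a gradient
norm with respect to critic parameters) is exact; convolutions are im2col
gathers plus one BLAS GEMM, with scatter-adds as cached sparse-matrix
products. First- and second-order gradients are verified against finite
differences and closed forms in the test suite.

## Reconstruction

Air correction is p = −ln(max(counts, floor)/air) with a 0.5-count floor
for zero-count pixels. FBP uses the band-limited spatial-domain ramp
(optionally Hann-apodized), linear detector interpolation, and a π/(2N_θ)
backprojection weight; dividing by the detector pitch (in cm) returns μ in
cm⁻¹. It agrees with an established reference implementation to ~10⁻³ and
reconstructs an analytic water disc with RMSE < 2% of μ_water. SART uses a
matched forward/adjoint pair built from the same Joseph sampling,
sequential view updates, relaxation 0.25 by default (clamped into (0,2)
with a warning) and 200 iterations by default; on a consistent full-rank
32×32 system with two rays per pixel it converges to the dense
least-squares solution to ~10⁻⁶. Both are parallel-beam only; cone-beam
geometries are out of scope.

## Image-domain denoising

TV denoising is Chambolle–Pock primal–dual with τ = σ = 1/√8 (satisfying
the τσ‖K‖² ≤ 1 bound for the discrete gradient), a fixed iteration budget
(default 18, deliberately not convergence-tested), λ = 1.0, and either an
L1 (default) or squared-L2 data term; isotropic TV is the default with an
anisotropic option whose exact optimum is checkable by linear programming.
On 16×16 instances the primal–dual objective lands within 10⁻³ of the LP
optimum when run long enough.

The guided filter follows the local linear model: per window
a_k = cov(I,p)/(var(I)+ε), b_k = mean(p) − a_k mean(I), output
q_i = mean over windows containing i of (a_k I_i + b_k). Windows are
(2r+1)² boxes with border truncation and actual-size normalization,
implemented with integral images and verified against brute-force window
enumeration to 10⁻¹⁰. Defaults r = 5, ε = 10⁻⁸. The "guiding iteration"
count (default 1000) is interpreted as repeated application of the filter
with the guidance held fixed — the filter is closed-form, so iteration can
only mean re-application; this reading is configurable.

The guidance image is the virtual integrating bin: pre-log counts summed
over all bins (taken before projection correction), air-corrected with the
summed air scan, reconstructed, and TV-denoised. For overlapping-bin data
the lowest-threshold bin plays this role instead. Summation minimizes
quantum uncertainty: on the simulated datasets the guidance image's
flat-region noise is below that of every single-bin reconstruction.

Material decomposition (a demonstration, not a calibrated method) solves a
per-voxel least-squares fit of the bin-wise μ vector onto basis columns
(packaged μ evaluated at bin centers; soft tissue and bone by default),
optionally with nonnegativity via NNLS.

## Metrics

RMSE is reported in the projection domain, PSNR/SSIM on reconstructed
images. SSIM uses the standard constants (K₁ = 0.01, K₂ = 0.03, Gaussian
window σ = 1.5) with the data range defaulting to the reference image's
dynamic range, recorded in the report. The NPS estimator mean-detrends the
ROI and scales |DFT|² by (pixel area)/N_pix, so the NPS integrated over
frequency equals the noise variance exactly; radial averages use coarse
annuli (≥ 8 bins, one per ~16 grid rings) to suppress ring-quantization
artifacts. One-way ANOVA is classical F with a defined (F=0, p=1) sentinel
for fully degenerate input; grouping of samples is the caller's choice.

## Problem sizes and what the experiments show

The shipped experiments run at desk scale: 32³/64³ phantoms, 30/60 views,
2000 patch pairs, 5 epochs, compact network widths — sizes chosen so the
entire suite, including four seeded training runs and the full dual-domain
chain, completes on one CPU in well under half an hour. At these scales the
experiments demonstrate the *mechanics* and *direction* of every effect
(the distortion chain biases counts; adversarial training with the combined
loss removes most of the bias; TV+GF with the integrating-bin guidance
raises SSIM in every energy bin) but not the absolute benchmark numbers of
a GPU-scale training campaign. The synthetic data also idealizes real
scanners: parallel beam, no scatter, no defective pixels, no ring
artifacts, a parametric rather than measured detector response, and
synthetic attenuation curves — passing tests therefore validate the
algorithms and their implementation, not clinical performance.

## Known limitations

- The pileup spectrum-shift kernel is a first-order doublet model; triplet
  and higher-order pileup shapes are folded into the doublet term.
- Batch normalization in the critic couples gradient-penalty samples within
  a batch (scores are per-sample independent only in evaluation mode).
- The numpy autodiff engine favors clarity over speed; full-scale widths
  train impractically slowly on CPU.
- Charge splitting between detector *rows* of different z-slices is modeled
  identically to in-plane cross-talk; no sub-pixel charge-cloud geometry.
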