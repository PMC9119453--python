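# Methods

## The restoration problem

A widefield microscope imaging a 3D sample can either pause at discrete
axial positions and collect a z-stack, or move continuously and integrate
light along the way (a z-sweep). The sweep is ~100× faster and deposits far
less light on the sample, but the image it produces mixes in-focus and
defocused contributions from the whole axial range. This package treats the
recovery of a high-quality 2D projection P from a sweep image S as a
supervised image-to-image problem: a convolutional generator G with
parameters θ is trained on paired acquisitions so that G(S) = P̂ ≈ P,
minimizing Σᵢ L(G(Sᵢ|θ), Pᵢ) over the training pairs.

## Acquisition model (`optics`)

The simulator is a forward model of the instrument, not instrument control.
A phantom is a set of uniform-emission spheres (center, radius, emission
rate in photons·μm⁻³·s⁻¹) in a volume, plus a flat background (photons per
pixel per second), in one of three assay layouts: a single centered
spheroid, many spheroids sharing one optical plane, or spheroids embedded
throughout the z extent.

For a focal plane at height z, the expected photon rate per pixel is

    exposure × (background + Σ_spheroids blur(column_density, σ(z)))

where column density is emission rate × chord length through the sphere ×
pixel area, and the point-spread function is an isotropic Gaussian with

    σ(z) = psf_sigma_focus + psf_defocus_slope · |z − z_object|.

No analytic PSF of the real optics is available; a width growing linearly
in defocus is the simplest monotone model that makes the restoration task
genuinely ill-posed (defocused planes are both blurred and diluted). Depth
attenuation and scattering are deliberately omitted. Each spheroid is
treated as lying at its center's z when blurring, which is accurate for
spheroids comparable to the 25.3 μm depth of field and a deliberate
simplification for larger ones.

The camera applies Poisson shot noise to expected photon counts, a linear
gain (1 ADU/photon by default), and 12-bit saturation per frame.

* **z-stack**: planes every `z_step` = 25 μm (within the 25.3 μm DOF);
  at each plane `frames_per_plane` = 3 consecutive 50 ms exposures are
  digitized independently and averaged. The averaged plane keeps the
  single-frame intensity scale, so its effective exposure is 0.05 s.
* **z-sweep**: continuous motion at 1250 μm/s while consecutive 50 ms
  exposures are summed. 1.25 mm/s × 50 ms = 62.5 μm of travel per frame;
  a 750 μm range gives 12 exposures, 1.5 mm gives 24 (effective exposure
  0.6 s / 1.2 s). Within each frame the motion is integrated by 10 midpoint
  sub-renders (~6.25 μm per sub-step, well below the DOF); against a
  10×-finer integration the resulting normalized image differs by ~10⁻⁵
  relative L2, far inside the 10⁻³ tolerance the tests enforce. Dead time
  between consecutive exposures is assumed zero. A sweep frame whose travel
  would pass the volume top clamps its focal position at the top.
* Both images are divided by effective exposure time (ADU/s) so S and P
  share one intensity scale — the property the pairing depends on.

Defaults chosen where the physical system leaves them open: pixel size
1.39 μm/px at full scale (plausible for a 4× objective and a 1536-px-wide
field); z = 0 at the well bottom, increasing upward.

## Ground-truth projection (`zproject`)

The projection collapses a stack by per-pixel plane selection. The focus
measure is local intensity variance in a 9×9 window (texture statistics of
this kind are the standard extended-depth-of-field construction; the
vendor's exact algorithm is proprietary, so this module is a stand-in built
to the same description). The per-pixel argmax index map is median-smoothed
with radius 4 to suppress speckle from noise-driven selections, then each
pixel samples its selected plane. Ties break toward the lower plane index
for determinism. Window edges use reflection. On simulated single-plane
phantoms this projection tracks the noiseless in-focus render with lower
mean absolute error than a max-intensity projection (tested).

## Architectures (`models`, `nn`)

The networks are built on `sweeprestore.nn`, a compact reverse-mode
autodiff engine over numpy arrays with the conv/pool/upsample/batch-norm
operations these models need, verified against central-difference gradients.

**U-Net generator.** `depth` (default 4) resolution levels; downsampling by
2×2 max pooling, upsampling by bilinear interpolation, skip concatenations,
and a linear 1×1 output head. Each level applies two [3×3 conv → batch
norm → ReLU] units (depth and widths are not pinned by the problem; depth 4
with 64 base channels is the canonical configuration, and two units per
level is the classic choice). Inputs must be divisible by 2^depth;
`predict` reflect-pads and crops otherwise.

**OSA-U-Net.** Each level's second unit is replaced by a one-shot
aggregation block: L = 3 chained 3×3 convolutions (ReLU between), the input
and all L intermediates concatenated once, a 1×1 convolution projecting
back to the input width, an efficient squeeze-and-excitation gate (global
average pool → 1×1 conv → hard sigmoid, with hard_sigmoid(x) =
clip((x+3)/6, 0, 1)) multiplying each channel, and a residual addition of
the block input. The block preserves channel count; channel changes happen
in the level's first unit.

**PatchGAN discriminator.** The sweep and the (real or predicted)
projection are stacked into a 2-channel input and passed through five 4×4
convolutions. The published description says stride 2 per block, but the
stated 70×70 px receptive field forces the pix2pix variant with the last
two layers at stride 1; the receptive field wins, so strides are
[2, 2, 2, 1, 1] with padding 1 (256×256 in → 30×30 patch grid). Batch norm
is omitted from the first and last layers (pix2pix convention); a final
sigmoid maps patch logits to probabilities, which keeps the discriminator's
codomain [0, 1] while the losses remain least-squares. The receptive field
is both computed by the backward recurrence RF ← (RF−1)·stride + kernel and
measured as the nonzero input-gradient footprint of one output unit; the
two must agree.

Weights initialize as N(0, 0.02) (pix2pix convention) from an exposed seed.
Batch norm uses batch statistics during training and running statistics at
inference; with batch size 2 the training statistics are noisy, which is
inherent to the configuration.

## Training (`training`)

Images are log-transformed (natural log, offset 1 ADU/s) for training;
unlike per-batch normalization this preserves the intensity relations
between images so the network learns absolute fluorescence levels.
Augmentation crops matched random windows (default 256×256, 4 per image)
and flips each axis with probability 0.25, identically for S and P.

The supervised loss is the pixel-sum L1 error (a sum, not a mean, as
defined; λ_L1 = 10 compensates the scale against the mean-based adversarial
terms). The adversarial losses are least-squares with one-sided label
smoothing: real labels R = 1 − U[0, 0.1] drawn fresh at every evaluation,
fake labels F = 0. Each mini-batch takes one generator step (discriminator
frozen — its parameters are simply never stepped in this phase) and one
discriminator step (generator frozen — the prediction is detached from the
generator's graph). Optimization is Adam (lr 2·10⁻⁴, β₁ = 0.9, β₂ = 0.999),
batch size 2, up to 1250 epochs, with the generator checkpointed at the
minimum validation L1 — also for the adversarial variants, whose validation
error is the supervised L1. Validation L1 is computed in the log (training)
domain as the mean per-image pixel sum.

`predict` applies log transform → generator (inference mode) → inverse log
transform and clips at zero, the physical lower bound.

## Metrics (`metrics`)

MSE, PSNR (10·log₁₀(L²/MSE), +inf for identical images), SSIM (Gaussian
window 11, σ 1.5, K₁ = 0.01, K₂ = 0.03, matched to scikit-image's
implementation at 10⁻⁶), MS-SSIM (five dyadic scales, exponents 0.0448,
0.2856, 0.3001, 0.2363, 0.1333; contrast-structure at all scales, luminance
at the coarsest; terms clipped at zero before the geometric mean), and FID
(Fréchet distance between Gaussian fits of feature embeddings, matrix
square root via scipy, ridge-regularized when singular). Metrics run on
linear-domain exposure-normalized images; the data range defaults to the
per-pair maximum of the ground-truth image — both configurable, since
nothing pins these choices and SSIM in particular depends strongly on the
assumed dynamic range. The FID feature extractor is injected; the default
is a frozen seeded random-projection + tanh embedding (deterministic,
self-contained), and an inception-style network can be supplied through the
same callable interface.

## Quantification (`quantify`)

Segmentation thresholds the image (Otsu by default, or an explicit value),
labels 8-connected components, removes objects under 1200 μm² (the debris
filter), and orders labels by descending area. For synthetic phantoms the
ground-truth projected-disc mask is available (`phantom_label_mask` +
`filter_labels`) and is preferred in tests, mirroring the use of one
independent mask applied to every image under comparison. Per object the
module reports area, mean linear intensity, and the sum of log-domain
intensities. Fidelity regression fits ordinary least squares on natural-log
intensities of the image under test against the reference, reporting slope,
intercept and R²; pairing is by mask identity. Time courses average objects
within an image, then report mean ± standard error across images per
day × condition.

## Desk-scale study conditions

Training the full-size models to convergence is a GPU-scale undertaking
(the real runs take ~1000+ epochs at 2·10⁻⁴), so the package's end-to-end
checks run a fixed desk-scale configuration: 32 synthetic single-plane
multi-spheroid pairs at 64×64 px (4 μm/px, 750 μm range; 6 spheroids of
radius 25–60 μm, emission 2–8 photons·μm⁻³·s⁻¹, background 100
photons·px⁻¹·s⁻¹), split 28/4, a depth-2 / 8-channel U-Net, 30 supervised
epochs at Adam lr 0.01, and a 5-epoch adversarial loop with a narrow
(8–16 channel) PatchGAN. The larger learning rate is a property of the
desk-scale configuration only: at the production rate the log-domain output
level drifts into place over hundreds of epochs, which is exactly what the
checkpointing regime expects at full scale. Under these conditions the
trained generator reaches roughly half the validation L1 of using the raw
sweep as the prediction, and per-spheroid restored mean intensities regress
onto the true-projection intensities with slope ≈ 0.94 and R² ≈ 0.998.

## What the synthetic data does and does not show

The simulator reproduces the features that make the mapping nontrivial —
defocus mixing, shot noise, saturation, the intensity-scale gap between
paradigms — but not scattering, depth-dependent attenuation, optical
aberrations, halo artifacts, or the morphology of real spheroid interiors.
Passing the desk-scale checks demonstrates that the training machinery
optimizes the stated objectives, that the acquisition model is
flux-consistent, and that restoration preserves per-object intensity
statistics under these idealized conditions; it does not certify
restoration quality on real instrument data, which additionally depends on
training scale and the fidelity of the optical model.

## Numerical choices and limitations

* Log offset 1 ADU/s; natural log throughout (regression and transform).
* Focus-score ties break toward the lower plane; labels order by area then
  first pixel; both for determinism.
* The sweep's per-frame motion integration uses midpoint sub-steps; the
  flux-consistency tolerance (10⁻³ vs a 10×-finer oracle) bounds the
  residual discretization error.
* Batch norm uses biased variance for both normalization and running
  statistics (momentum 0.1).
* PSNR of identical images is reported as +inf and excluded from set means.
* The engine is CPU-only float64 numpy; it is sized for desk-scale
  experiments and small production runs, not GPU-scale training.
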