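# sweeprestore

High-throughput widefield fluorescence imaging of 3D samples — spheroids,
organoids — normally requires a z-stack: dozens of pausing exposures along
the axial dimension, later collapsed into a single 2D projection. A
continuous axial **z-sweep** acquires the same volume in a single pass
(1.5 mm in 1.2 s at 1.25 mm/s versus ~100 s for the stack), but the
resulting integrated image is dim and blurry. `sweeprestore` implements the
full workflow that makes z-sweeps usable for quantitative biology:

* a **paired-acquisition simulator** — synthetic 3D spheroid phantoms imaged
  under both paradigms with a defocus-dependent Gaussian PSF, Poisson shot
  noise and a 12-bit camera model, both outputs normalized by effective
  exposure time;
* a **texture-based extended-depth-of-field projection** that builds the
  ground-truth image P from a z-stack by per-pixel selection of the
  most-textured plane;
* **restoration generators** G : S ↦ P̂ — a standard U-Net and an
  OSA-U-Net whose levels use one-shot-aggregation blocks with efficient
  squeeze-and-excitation gates — plus a 70×70-receptive-field **PatchGAN**
  discriminator, all built on a compact numpy autodiff engine shipped in
  `sweeprestore.nn`;
* **training objectives**: the supervised pixel-sum reconstruction error
  L_L1(P, P̂) = Σᵢⱼ |Pᵢⱼ − P̂ᵢⱼ|, and the least-squares conditional-GAN pair

      L_G = λ_L1 · L_L1(P, P̂) + E[(D(S, P̂) − R)²]
      L_D = ½ · E[(D(S, P) − R)² + (D(S, P̂) − F)²]

  with one-sided label smoothing R ∈ [0.9, 1], F = 0, alternating
  generator/discriminator updates (Adam, lr 2·10⁻⁴, batch 2, λ_L1 = 10),
  log-domain images, and checkpointing on minimum validation L1;
* **evaluation**: MSE, PSNR, SSIM, MS-SSIM and FID with an injectable
  feature extractor;
* **quantification**: per-spheroid intensity statistics under a segmentation
  mask, log-scale fidelity regression (slope / R² of restored vs. true
  per-object intensities), and treatment time-courses with the 1200 μm²
  debris area filter.

## Worked example

```python
import numpy as np
from sweeprestore.datasets import default_spec_for_size, generate_dataset
from sweeprestore.models import GeneratorSpec
from sweeprestore.training import TrainSpec, augment, train, predict, log_transform
from sweeprestore.quantify import fidelity_regression, filter_labels, measure_objects
from sweeprestore.optics import PhantomParams, phantom_label_mask

spec = default_spec_for_size((64, 64))            # 64x64 px at 4 um/px, 750 um range
params = PhantomParams(n_spheroids=6, radius_range=(25, 60),
                       emission_range=(2, 8), background_rate=100)
pairs, _ = generate_dataset("single_plane_multi", 32, (64, 64), seed=11,
                            spec=spec, params=params)

tspec = TrainSpec(max_epochs=30, crop_size=64, learning_rate=0.01, seed=0)
rng = np.random.default_rng(0)
train_pairs = [c for p in pairs[:28] for c in augment(p, tspec, rng)]
val_pairs = [c for p in pairs[28:] for c in augment(p, tspec, rng)]
ckpt, hist = train(train_pairs, val_pairs,
                   GeneratorSpec(depth=2, base_channels=8), tspec)

baseline = np.mean([np.abs(log_transform(p.P) - log_transform(p.S)).sum()
                    for p in pairs[28:]])
print(f"identity baseline {baseline:.0f}, best validation L1 {ckpt.validation_l1:.0f}")

# per-spheroid fluorescence fidelity on noiseless phantoms
eval_pairs, eval_ph = generate_dataset("single_plane_multi", 6, (64, 64),
                                       seed=77, spec=spec, params=params, noise=False)
truth, pred = [], []
for pair, ph in zip(eval_pairs, eval_ph):
    mask = filter_labels(phantom_label_mask(ph, spec), 1200.0, spec.pixel_size)
    if mask.max() == 0:
        continue
    truth += [r.mean_intensity for r in measure_objects(mask, pair.P, spec.pixel_size)]
    pred += [r.mean_intensity for r in measure_objects(mask, predict(ckpt, pair.S),
                                                       spec.pixel_size)]
fit = fidelity_regression(truth, pred)
print(f"fidelity: slope {fit.slope:.3f}, R^2 {fit.r_squared:.3f} over {fit.n_points} spheroids")
```

Output from this exact run:

```
identity baseline 2401, best validation L1 1072
fidelity: slope 0.942, R^2 0.998 over 30 spheroids
```

The trained generator more than halves the reconstruction error of using
the raw sweep directly, and the per-spheroid mean intensities it restores
fall on the identity line of the log-scale scatter against the true
projection — the property that makes the restored images usable for
intensity-based viability readouts.

The same workflow is scriptable from the shell:

```sh
sweeprestore simulate --layout multi --n-pairs 8 --size 128x128 --seed 1 --out data/
sweeprestore train --data data/ --arch osa-unet --adversarial --out model.npz
sweeprestore predict --ckpt model.npz --in data/pair000_sweep.tif --out restored.tif
sweeprestore evaluate --pred preds/ --truth truths/ --report table.tsv
sweeprestore quantify --image restored.tif --pixel-size 4 --min-area 1200 --out objects.csv
```

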