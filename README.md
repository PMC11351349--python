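# dwicycle

Unpaired CycleGAN synthesis of high b-value gastric diffusion-weighted
MRI (DWI), with the full evaluation stack a study of such a model needs:
lesion-weighted image-quality metrics, two-point ADC mapping, and
ICC-based reader-agreement analysis — plus a physics-grounded phantom
generator that makes every stage testable without clinical data.

## The problem

High b-value DWI (b = 1200 s/mm²) gives the best tumor-to-background
contrast in gastric cancer imaging: restricted diffusion keeps tumor
signal high while free water is suppressed. But high-b acquisitions are
noisy and slow — more signal averages are needed to keep SNR up, which
lengthens scan time and invites motion artifacts. This package trains
an unpaired image-translation model that synthesizes b = 1200 images
(*s-DWI*) from faster, lower b-value acquisitions (*a-DWI*, b = 800),
using real b = 1200 images (*b-DWI*) only as an unpaired style
reference.

## The model

A CycleGAN: generators G: A→B and F: B→A with patch discriminators Dx,
Dy, trained with the least-squares adversarial loss and an L1 cycle
penalty λ·(‖x − F(G(x))‖₁ + ‖y − G(F(y))‖₁), λ = 10, Adam β₁ = 0.5,
batch size 1, five generator iterations per discriminator iteration.
Three additions distinguish it from the plain recipe:

- **ViT bottleneck** — the coarsest U-net feature grid is flattened
  into tokens, concatenated with a 2D Fourier positional embedding, and
  run through 12 rezero transformer encoder blocks
  (out = in + α·branch(in), α trainable, initialized at 0 so the stack
  is the identity at initialization).
- **CBAM attention** — each encoder/decoder block applies a channel
  gate sigmoid(MLP(avgpool) + MLP(maxpool)) then a spatial gate
  sigmoid(conv([mean; max])).
- **Dual-contrast discriminator loss** — each discriminator also labels
  raw *source-domain* images as fake:
  L_D = mean((D(real) − 1)²) + mean(D(fake)²) + w·mean(D(source)²),
  which pushes the generator away from the source domain in latent
  space. All three are toggleable for ablations (`--no-vit`,
  `--no-cbam`, `--no-dcl`).

Evaluation uses PSNR/MSE/SSIM/FSIM plus weighted variants WPSNR/WMSE
driven by a normalized lesion-weight matrix, and the clinical
downstream quantity: the apparent diffusion coefficient from the
two-point method, ADC = ln(S₅₀/S₁₂₀₀)/(1200 − 50) mm²/s, read out in
circular ROIs and assessed with ICC(2,1) (two-way random effects,
absolute agreement, single measurement, Shrout–Fleiss CIs).

Everything runs on the CPU: the networks are built on a small float64
reverse-mode autodiff engine (`dwicycle._autodiff`), which keeps
training runs bit-reproducible from a single seed.

## Worked example: phantom → signal → ADC

```python
import numpy as np
from dwicycle import Tissue, compute_adc, generate_scene, simulate_signal
from dwicycle.adc_analysis import RoiCircle, roi_mean

scene = generate_scene((128, 128), n_lymph_nodes=2, lesion_extent=0.2, seed=7)
low = simulate_signal(scene, 50.0)     # S(b) = S0 * exp(-b * ADC)
high = simulate_signal(scene, 1200.0)
adc = compute_adc(low, high)           # two-point inversion
for tissue in (Tissue.LESION, Tissue.STOMACH_WALL, Tissue.LUMEN_WATER):
    val = np.nanmean(adc.values[scene.labels == tissue]) * 1e3
    print(f"{tissue.name.lower():13s} ADC = {val:.2f} x 10^-3 mm^2/s")
rows, cols = np.where(scene.lesion_mask)
roi = RoiCircle((rows.mean(), cols.mean()), radius=3.0)
print(f"circular-ROI mean ADC at lesion centroid: {roi_mean(adc, roi)*1e3:.2f} x 10^-3 mm^2/s")
```

prints

```
lesion        ADC = 0.94 x 10^-3 mm^2/s
stomach_wall  ADC = 1.54 x 10^-3 mm^2/s
lumen_water   ADC = 2.88 x 10^-3 mm^2/s
circular-ROI mean ADC at lesion centroid: 1.08 x 10^-3 mm^2/s
```

— the tumor restricts diffusion (low ADC, bright at high b), free water
in the stomach lumen diffuses fastest (high ADC, suppressed at high b),
and the ROI mean mixes the lesion with adjacent wall. The two-point
inversion recovers the phantom's hidden ADC map exactly (to float
precision) on noiseless input.

## Command-line pipeline

```sh
dwicycle simulate --subjects-train 6 --subjects-test 2 --size 32 --seed 1 --out data/
dwicycle train --data data/ --out run/ --seed 1
dwicycle synthesize --checkpoint run/checkpoint_final.npz --in data/testA --out synth/
dwicycle evaluate --pred synth/ --ref data/testB --out report.csv
dwicycle adc --low low/ --high high/ --out adcmaps/
dwicycle icc --table readings.csv --design between_readers
```

`simulate` writes unpaired `trainA` (noisy, distorted b = 800) and
`trainB` (cleaner b = 1200) domains, test folders, a hidden `truth/`
folder of paired noiseless slices for evaluation only, and a
`manifest.yaml` with seeds, checksums and the global intensity maximum
(so 16-bit PNG quantization is invertible).

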