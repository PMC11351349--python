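# Methods

This note records the models, the numerical choices, and the open
design decisions behind `dwicycle`, in the order the pipeline runs.

## Phantom model (`synthetic_dwi`)

The phantom emulates a 2D axial upper-abdomen slice: an elliptical
stomach whose wall annulus carries a tumor arc, a water-filled lumen,
a liver ellipse, and up to a few circular perigastric lymph nodes on a
fat background. Geometry is parametric with small seeded jitter per
scene; no anatomy atlas is involved.

**Signal model.** Mono-exponential decay, S(b) = S0·exp(−b·ADC), per
pixel. This is the model the two-point ADC formula presupposes; since
the clinical protocol being emulated computes ADC exactly that way,
adopting it makes the simulator and the analysis mutually consistent
by construction. No perfusion (IVIM) or kurtosis terms are simulated,
so low-b signal lacks the pseudo-diffusion spike real tissue shows —
a deliberate limitation: the package's ADC code would attribute any
such component to noise, exactly as a clinical two-point protocol does.

**Tissue table.** Defaults (S0 in arbitrary units, ADC ×10⁻³ mm²/s):
lumen water (1.0, 3.0), liver (0.8, 1.2), stomach wall (0.7, 1.6),
lesion (0.9, 0.9), lymph node (0.85, 1.0), background (0.05, 2.0).
Values are chosen to reproduce the qualitative contrast that motivates
high-b imaging — tumor ADC below wall below free water, so the lesion
is the brightest soft tissue at b = 1200 while the lumen is suppressed.
The table is overridable per call; the strict ordering
ADC(water) > ADC(wall) > ADC(lesion) is enforced even under jitter.

**Noise.** Magnitude-MRI noise is Rician: v → sqrt((v+n₁)² + n₂²),
n₁, n₂ ~ N(0, σ²). The per-b-value level is base_sigma/√(averages)
with the averages ladder 2/4/6 at b = 50/800/1200, mirroring a
clinical gastric protocol where higher b-values get more averages.
Default base_sigma = 0.10 relative to the unit-S0 scale, i.e. an SNR
of roughly 8 in b = 800 soft tissue — visibly noisy, as the premise of
the translation task requires. Domain A (b = 800) additionally gets a
smooth random displacement field along one axis (default max 1 px,
emulating echo-planar geometric distortion); domain B does not. This
asymmetry gives the generator something physically meaningful to
correct and mirrors the clinical claim the model targets (synthetic
high-b should *improve on* acquired lower-b).

**Reproducibility.** Every random draw is seeded through one rule,
`derive_seed(root, *tags)` = SHA-256 of the tag tuple mod 2³¹, so a
manifest seed reproduces a dataset byte-for-byte. Images are stored as
16-bit PNG, quantized against a recorded global maximum so the
normalization is invertible; the hidden `truth/` folder holds paired
noiseless b = 1200 and b = 50 slices for evaluation and ADC work.

## Generator (`generator_net`)

Four-level U-net: a 7×7 preprocessing convolution to f0 channels, then
four stride-2 3×3 convolution blocks, each halving H,W and doubling
channels, with instance normalization, ReLU and CBAM. The decoder
mirrors with transposed convolutions (k3, s2, output padding 1),
concatenating the pre-downsample skip tensor at each level; a final
7×7 convolution and tanh map to [−1, 1]. Downsampling by strided
convolution, instance norm, and the tanh output range follow standard
CycleGAN practice; they are conventions, not discoveries.

**ViT bottleneck.** The (H/16, W/16, f0·16) grid is flattened to
tokens, each concatenated with a 2D Fourier positional embedding:
for pixel (i, j) normalized to [0, 1) — half-open, so the periodic
basis never aliases opposite edges onto the same code — the embedding
stacks sin/cos of 2π·s·i and 2π·s·j over fp/4 geometric frequencies
s ∈ {1, 2, 4, …}. Tokens are projected to width fv, run through
`vit_blocks` pre-norm transformer encoder blocks with rezero residual
scaling (one trainable α per branch, initialized to 0, making the
stack the identity between its projections at initialization — the
property the rezero tests pin down), projected back and unflattened.
Defaults fv = 512, fp = 64, 8 heads, 4× MLP are standard small-ViT
values; the architecture source specifies only the 12-block depth, so
these widths are this package's choices and all are configurable.

**CBAM.** Channel gate sigmoid(MLP(avgpool) + MLP(maxpool)) with a
shared two-layer MLP (reduction 8), then spatial gate
sigmoid(conv7×7([channel-mean; channel-max])). Placed after the
convolution in every encoder *and* decoder block — where exactly the
attention block sits was an open choice; both paths was chosen so the
ablation toggle removes a well-defined parameter group. Gates are
strictly inside (0, 1), so CBAM can only attenuate.

## Adversarial core (`adversarial_core`)

Patch discriminators: 4 convolution layers (4×4 kernels, strides
2/2/2/1, instance norm, leaky-ReLU 0.2) plus a 1-channel head — the
standard 70×70-receptive-field design; 256×256 in, 30×30 logits out.

**Losses.** Least-squares adversarial form by default (cross-entropy
available behind `adv_loss`). The dual-contrast discriminator loss
adds mean(D(source)²) with weight `neg_weight` (default 1; the weight
between fake and negative terms is unspecified upstream, so equal
weighting is the neutral choice). Negatives are drawn uniformly at
random from the opposite-domain pool at every discriminator step, for
both discriminators symmetrically. Cycle loss is L1 with λ = 10.
Identity loss and a fake-image history buffer are off by default
(flags exist); neither is part of the protocol being implemented.

**Protocol.** Adam with β₁ = 0.5 (the single "β" the protocol names is
read as Adam's first-moment decay; β₂ = 0.999), learning rate 2×10⁻⁴
constant for the first half of training then decaying linearly, batch
size 1, 200 epochs at full scale. Five generator updates — on fresh
random batches, the interpretation adopted for "five iterations" —
are followed by one discriminator update. Discriminators are frozen
(no gradient accumulation) during generator updates and fakes are
detached during discriminator updates, so the two players' gradients
are provably isolated; the autodiff engine only propagates into
tensors flagged as requiring gradients, which makes this contract
testable. A non-finite loss aborts training and dumps the offending
batch for forensics. Training is single-threaded float64, so a seed
fully determines the loss log.

**Scales.** Full scale (256×256, f0 = 64, 12 ViT blocks, ndf = 64,
200 epochs) is the faithful configuration; on a plain CPU it is a
multi-day run and is not exercised by the tests. The desk scale used
throughout testing and in `scripts/acceptance.py` is
`scaled_down_configs()`: 32×32 phantoms, f0 = 8, one ViT block,
fv = 64, ndf = 16, 600 generator updates at lr 10⁻³. The protocol
(batch 1, λ = 10, β₁ = 0.5, 5:1 ratio, dual-contrast negatives) is
unchanged; only widths, resolution and duration shrink. What the
passing desk-scale tests show is that the implementation learns the
intended mapping (denoise + b-value contrast transform) and that the
synthesized images beat the acquired baseline on held-out subjects;
they do not certify clinical-scale image quality.

## Quality metrics (`quality_metrics`)

MSE/PSNR are standard, with +inf as the documented PSNR sentinel for
identical images and the data range taken from the dataset manifest
(not per-image maxima) so scores are comparable across images. The
weighted variants take a normalized nonnegative weight matrix;
`weight_from_mask(mask, ratio)` gives lesion pixels `ratio`× the
background weight (default 4) and normalizes to sum 1. The numeric
weights a clinical expert would assign are unknowable from outside;
the ratio is therefore an explicit knob, not a reconstruction, and
uniform weights provably collapse WMSE/WPSNR onto MSE/PSNR.

SSIM uses the original constants (K1 = 0.01, K2 = 0.03, 11×11
Gaussian window σ = 1.5, no sample-covariance correction), averaged
over the interior region the window fully covers; it matches
scikit-image's implementation to ~1e-16.

FSIM is implemented from its published definition: phase congruency
from a 4-scale × 4-orientation log-Gabor bank (min wavelength 6,
multiplier 2, σ_onf 0.55, angular spread 1.2, Rayleigh noise threshold
k = 2 with the published 1/1.7 overlap correction), Scharr gradient
magnitude, similarity constants T1 = 0.85 and T2 = 160 on the 0–255
scale (inputs are rescaled internally), pooled by maximum phase
congruency; luminance-only, as DWI is grayscale. Large images are
box-averaged and subsampled by round(min(H,W)/256) per the published
procedure. The test suite checks it against a structurally independent
transcription of the same published algorithm; the two agree to
machine precision on random pairs.

## ADC and ICC (`adc_analysis`)

Two-point ADC = ln(S_low/S_high)/(b_high − b_low) per pixel, computed
only where both signals exceed 10⁻⁶ of the data maximum; nonpositive
pixels are masked invalid rather than clamped, because clamping drags
ADC toward zero in exactly the low-signal regions a reader would
measure. ROI means use pixel centers strictly inside the circle — the
convention is documented because ROI means depend on it.

The reader-study simulator adds per-reader bias, per-session shift and
per-repetition noise (all Gaussian, seeded) to per-subject truth, in
the triplicate two-session two-reader layout of the emulated protocol.

ICC form: the upstream protocol says only "ICC"; ICC(2,1) — two-way
random effects, absolute agreement, single measurement — is the
standard choice for inter-reader absolute-agreement studies and is
what this package computes, from the two-way ANOVA mean squares after
averaging triplicates per (subject, rater) cell. Confidence intervals
are the Shrout–Fleiss F-based intervals (the upstream CI method is
unnamed; these are the textbook default). Consistency between readers
uses session-1 data with readers as raters; repeatability uses one
reader's two sessions as raters. Because the published agreement
tables depend on an unknown ICC variant and a private cohort, they are
treated as qualitative anchors, not numeric targets.

## Numerical and engineering choices

- All tensor math is float64 on the CPU via a package-local
  reverse-mode autodiff engine (im2col convolutions, batched matmul
  attention, composite-op normalization layers, Adam). Float64 plus
  single-threaded execution is what makes "same seed, same loss log"
  an exact statement rather than a tolerance.
- Convolution backward passes recompute their im2col buffers instead
  of caching them; peak memory stays modest even at 256×256.
- Softmax subtracts a detached row maximum (exact for value and
  gradient); max-gradients route to the first argmax on ties.
- Degenerate inputs fail loudly with named structures: scenes too
  small for the stomach or a requested lymph node, image sizes not
  divisible by 2^depth, unbalanced ICC tables listing their missing
  cells, ROIs with no valid pixel.
- The interchange formats are 16-bit PNG (images), float32 NIfTI (ADC
  maps, with pixel spacing), CSV (reports, reader tables, loss logs)
  and YAML (configs, manifests). DICOM ingestion is out of scope.

## Known limitations

- The phantom is 2D, single-coil, motion-free and atlas-free; it
  validates algorithmic correctness, not clinical performance.
- Mono-exponential signal means no perfusion/kurtosis confounds in
  ADC; real two-point ADC inherits both.
- The full-scale 256×256/200-epoch configuration is documented but not
  routinely run on CPU; desk-scale results establish learning
  behavior, not radiological image quality.
- FSIM reference agreement is against an independent transcription of
  the published algorithm, since no third-party FSIM implementation is
  part of the package's dependency set.
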