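# Methods

`sctforge` is a desk-scale toolkit for studying how the composition of the
training loss affects CBCT-to-synthetic-CT image translation, and for
evaluating synthetic CTs with both conventional similarity metrics and a
feature-level statistic (the feature mapping ratio, FMR), plus gamma-index
dosimetry. Because no public paired CBCT/CT dataset or Monte-Carlo dose
engine is available at desk scale, a seeded phantom simulator provides
paired data with the statistical structure the method assumes, and every
claim the test suite makes is a property of the algorithms, not of clinical
data.

## Phantom simulator

Each case is a 2-D axial head-like slice built from randomized nested
ellipses: air background (−1000 HU), a skull ring (700–1200 HU), brain
soft tissue (20–50 HU), two to four low-contrast lesions (±10–30 HU around
brain), and one or two air cavities. Boundaries are softened with a 0.8 px
Gaussian (partial-volume-like) and values clipped to the 12-bit CT range
[−1024, 3071] HU. Default grid: 270 × 270 at 1 mm (configurable down to
32–64 px for tests). All geometry derives from
`default_rng([seed, case_index])`, so one seed reproduces a dataset
bit-for-bit.

The CBCT copy degrades the same anatomy with the classic cone-beam artifact
families, in order:

1. **Cupping/shading**: a multiplicative low-frequency bias field
   `1 + a·B(r)` where `B` combines a radial second-order polynomial with
   seeded noise smoothed at correlation length `bias_scale` (40 px),
   normalized to max |B| = 1 and scaled by local density, so air is
   unaffected and water-equivalent tissue shifts by up to
   `bias_amplitude` (35 HU).
2. **Scatter haze**: `scatter_fraction` (0.02) of the wide-blurred
   (σ = size/8) object signal added back.
3. **Noise**: additive Gaussian, `noise_sigma` = 12 HU.
4. **Calibration shift**: constant `hu_shift` = 12 HU.

Anatomy is never displaced (pairs are born aligned; registration is out of
scope). Defaults were chosen once so the uncorrected MAE(CBCT, CT) lands in
the 20–60 HU band — roughly an order of magnitude above the few-HU residual
a trained network should reach, leaving measurable headroom. What the
phantom does **not** emulate: real scatter physics, beam hardening,
truncation, deformable anatomy differences between scan dates, or 3-D
cone-beam geometry. Passing tests therefore demonstrate algorithmic
correctness and the relative behaviour of loss compositions, not clinical
performance.

Dose grids are a superposition of 2–5 anisotropic Gaussian "beam" lobes
centred inside the anatomy, normalized to max 1.0. An evaluated grid is the
reference shifted, scaled, and corrupted with proportional noise — a
controllable surrogate for synthetic-CT-induced dose error. In the ablation
harness the perturbation is coupled to the measured image error of each
synthetic CT (scale `1 + MAE/2000`, proportional noise `MAE/2000`, MAE in
HU), so better image agreement yields better gamma statistics; this
reproduces the ordering such an experiment probes without claiming dose
physics.

## Losses

Images are clipped to [−1000, 2000] HU and mapped affinely to [−1, 1]
before entering any loss (dynamic range L = 2); bounded inputs stabilize
the SSIM constants and training.

* **L1**: mean absolute difference, resolution-independent.
* **SSIM**: the standard similarity
  `((2 μx μg + c1)(2 σxg + c2)) / ((μx² + μg² + c1)(σx² + σg² + c2))`
  with `c1 = (0.01 L)²`, `c2 = (0.03 L)²` (the universal convention; the
  stabilisation constants are otherwise unspecified). Default is mean
  local SSIM over an 11 × 11 Gaussian window (σ 1.5, valid region); a
  `global` mode evaluates the formula once from image-wide moments. The
  trainable loss is `1 − SSIM` (the similarity is to be maximized).
* **Perceptual**: mean squared Euclidean distance between feature maps of
  a fixed convolutional extractor, averaged over the selected stages. The
  default extractor is a four-stage seeded-random stack
  (conv3×3 → ELU → 2×2 max-pool; 8/16/32/64 channels, He-initialized from
  a package-constant seed), so no pretrained weights are ever downloaded;
  an adapter accepts externally trained (e.g. VGG) convolutional weights.
  Fixed random features preserve the contract — a distance in a nonlinear
  multi-scale feature space — at desk scale. Which stages to use is
  configurable (default: all four) since no canonical layer choice exists.

The four compositions L1, LP (L1+perceptual), LS (L1+SSIM) and LPS (all
three) are weighted sums; weights default to 1.0 each ("well-balanced").

## Network

An FC-DenseNet: initial 3×3 convolution; `n_pool` dense blocks each
followed by a transition-down of exactly batch-norm, ELU, 1×1 convolution,
dropout p = 0.2, and 2×2 max-pooling; a bottleneck dense block; `n_pool`
transition-ups (2×2 stride-2 transposed convolution) each followed by a
dense block concatenating the skip features of the matching resolution; and
a final 1×1 convolution. Dense layers are BN → ELU → 3×3 conv → dropout,
each adding `growth_rate` feature maps; only a block's new feature maps are
upsampled. Exact depth/growth are free parameters of the architecture
family: the full preset is FC-DenseNet56-like (n_pool 5, growth 12,
4 layers/block), the `tiny` preset (n_pool 2, growth 8, 3 layers/block,
16 first channels, ~80 k parameters) is sized for CPU experiments. Inputs
not divisible by `2^n_pool` (e.g. 270 with five poolings) are
reflect-padded and cropped back. An optional global residual connection
(`residual=True`) adds the input to the output so the network learns the
artifact **correction**; for artifact-removal this starts training at the
identity and concentrates capacity on the degradation, which is what the
scaled-down experiments use.

The network, its autodiff engine (`sctforge.nn`), and Adam are implemented
in numpy (float32, im2col convolutions). Everything is deterministic given
the seeds: parameter init from `NetworkConfig.seed`, dropout masks and
batch order from `TrainConfig.seed`.

## Training protocol

Adam (β = 0.9/0.999), default initial learning rate 2e-5 and 150 epochs at
full scale. On-the-fly augmentation applies horizontal flip and random
rotation (±10°, bilinear, −1000 HU fill) with identical parameters to input
and target, and random Gaussian blur to the **input only** — blur emulates
imaging degradation, so blurring the target would change the learning
objective. Model selection keeps the best-validation-MAE checkpoint (no
selection rule is canonical; last-epoch is noisier). Loss components are
summed raw; per-component values are logged each epoch so any imbalance is
visible.

### Scaled-down study conditions

The CPU-scale recovery experiment (also what `scripts/acceptance.py` runs)
uses: 40 training / 10 held-out pairs at 64 × 64, tiny preset with the
residual connection, LPS loss, batch 4, learning rate 1e-3, 30 epochs.
The learning rate is scaled up from the full-protocol 2e-5 in proportion to
the drastically reduced schedule (150 → 30 epochs, thousands of slices →
40); with ~300 optimizer steps the full-protocol rate would barely move the
weights. Success criterion: held-out MAE(sCT, dCT) at most half the
uncorrected MAE(CBCT, dCT).

## Evaluation metrics

MAE is computed in HU over the whole slice by default; an optional body
mask (HU > −400, largest connected component) is provided because the air
background common to both images inflates similarity. PSNR uses a fixed
3000 HU data range (the clip-window width) so values are comparable across
cases; per-image ranges would not be. SSIM evaluation delegates to the loss
implementation with a 3000 HU data range. Aggregates are mean ± sample
standard deviation (n−1) across cases; metrics are computed per slice and
averaged.

## Feature mapping ratio

FMR follows the KAZE/A-KAZE family. A nonlinear scale space evolves the
min-max-normalised image through diffusion times `t = σ²/2` for
`σ_i = 1.6·2^(i/4)`, 12 levels (3 octaves × 4 sublevels, no subsampling),
using conservative explicit steps (τ ≤ 0.24, below the 0.25 2-D stability
limit) of `div(g∇L)` with Perona–Malik `g2 = 1/(1+|∇L|²/k²)` conductance
and zero-flux boundaries (the total intensity sum is conserved to round-off).
The contrast parameter k is the 70th percentile of the gradient magnitude,
floored at 0.01 so nearly flat images still diffuse. **When two images are
compared, k is estimated from the first (synthetic) image and shared**:
letting each image adapt its own k would diffuse a degraded image harder
and mask the degradation the metric exists to measure.

Keypoints are 3×3×3 extrema of adjacent-level difference images with
|response| > 1e-3, an 8 px border margin, sorted by |response| and capped
at 2000. Descriptors are 256 pairwise comparisons ("p brighter than q")
of 48 sub-region statistics — mean intensity and mean first derivatives
over a 4×4 cell grid sampled (12×12 bilinear samples) from a patch of
half-width max(4, 3σ) at the keypoint's own evolution level. The
comparison schedule is drawn once from a package-constant seed, so
descriptors are identical across runs and machines; comparisons of means
make descriptors invariant to global intensity offsets. Matching is brute
force: candidates are descriptor pairs minimal in both their row and their
column of the Hamming-distance matrix (mutual-nearest, all ties kept),
resolved one-to-one greedily by increasing (distance, index) and accepted
when the normalised distance (fraction of differing bits) is below the
threshold, default 0.8. (The published threshold "0.8" is read as
normalised distance — 0.8 raw bits would be degenerate; a Lowe-ratio mode
is provided as the alternative reading.) FMR = matched / detected, with
"detected" defaulting to the first (synthetic) image's count; `min` and
`mean` denominators are exposed because the convention is ambiguous.
The detector is difference-of-adjacent-nonlinear-levels — the published
description mixes difference-of-Gaussian language with a nonlinear scale
space; differencing the nonlinear levels honours both at once. Descriptor
bit length (256) and the detection threshold are configurable defaults,
not claims about the original implementation.

## Gamma index

Global normalization to the reference maximum; low-dose cutoff 10% of that
maximum (the dominant clinical convention; both configurable). For each
reference point above cutoff the evaluated dose is searched on a fine
lattice (steps of DTA/10) within a radius of 3×DTA, with linear
interpolation, scanning offsets by increasing radius with an early exit
once the distance term alone exceeds every point's current γ². Criteria
1%/1 mm and 2%/2 mm, 2-D per slice by default (3-D supported). The
absolute dose difference is the mean |eval − ref| / max(ref) over
above-cutoff points (dimensionless, ~0.01 magnitudes). An exhaustive
per-point brute-force search over the same lattice serves as the
independent oracle in the tests and agrees with the fast path to 1e-6.

## Numerical notes and limitations

* Training computation is float32; evaluation metrics (MAE/SSIM/PSNR,
  gamma, FMR) are float64.
* The L1 subgradient at zero is taken as 0.
* Nearest-neighbour ties in matching break to the lowest index; keypoint
  ordering is deterministic, so FMR is reproducible bit-for-bit.
* `generate_dose_pair` shifts by linear interpolation; sub-pixel shifts
  slightly smooth the evaluated grid.
* 2-D slices only; volumes are stacks of slices. No GAN/adversarial
  losses, no deformable registration, no dose calculation.
* Conclusions transfer to real CBCT only insofar as the artifact model
  (smooth multiplicative bias + haze + noise + offset) captures the real
  degradation; structured artifacts (streaks, rings, truncation) are not
  modelled.
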