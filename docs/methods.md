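# Methods

`hemaseg` implements a cross-phase segmentation method for liver
hemangiomas in non-contrast CT and exercises it end to end on a synthetic
paired-phase phantom. This note documents the model, the assumptions, the
parameters that matter, and the choices made where the design was open.

## Problem setting

Hemangiomas are conspicuous in portal-venous-phase CT (strongly hypodense
relative to enhanced parenchyma) but subtle without contrast agent. The
method transfers what can be learned from the venous phase to the
non-contrast segmentation task through three components:

1. **Wavelet edge enhancement (WEEM).** Each normalized slice is split by
   a one-level 2-D DWT into LL/LH/HL/HH subbands; the two directional
   detail bands are amplified by factors λ₁ (LH) and λ₂ (HL) and the image
   is reconstructed. Defaults: Symlet-4, λ₁ = λ₂ = 2.0, chosen on a grid
   [1.3, 2.2] in steps of 0.1. LL is untouched to preserve anatomy, HH to
   avoid boosting diagonal noise.
2. **Gaussian position-sensitive attention (GPSA).** With mask guidance,
   tumor-region statistics μ, σ (stabilizer ε = 10⁻⁵) of the channel-mean
   encoder feature map define a multi-scale Gaussian weight
   G = ⅓ Σ_k exp(−(I−μ)²/(2(kσ)²+ε)), k ∈ {0.5, 1, 2}. Flattened into g,
   the weights enter every attention layer as an additive rank-1 bias
   λ·ggᵀ on the logits, with λ a single learnable scalar (init 0.5) shared
   across heads and layers. A BCE supervision loss ties attention rows to
   the binary token-level tumor target with weight α = 0.3. At inference,
   per-case statistics are replaced by population averages of μ and σ
   accumulated over the training set.
3. **Pre-train / freeze / transfer.** Phase 1 trains the full model on
   venous-phase images with the soft Dice loss. The venous-branch encoder
   is then frozen (θ = θ*), and phase 2 adapts the remaining modules on
   paired data with L_total = L_Dice + α·L_attention.

The network is a dual-branch hybrid: two 4-layer stride-2 CNN encoders
(3×3 kernels, channel schedule base·{1,2,4,8}); the venous branch feeds a
linear token projection (learned positional embeddings added) into a
pre-norm transformer encoder (defaults 12 layers / 8 heads; 4× MLP
expansion); the non-contrast branch feeds the Gaussian weights and the
decoder skips. The decoder performs four rounds of 2× bilinear upsampling,
skip concatenation and a 3×3 stride-1 ReLU convolution, then a 1×1
two-class head. Skips are the three innermost non-contrast encoder stages
plus, at full resolution, the (enhanced) non-contrast input itself — the
encoder produces no full-resolution map, so the input image is the natural
fourth skip.

## Numerical backend

The network and its training loop run on a small reverse-mode autodiff
engine over float64 numpy arrays (`hemaseg.autodiff`), with convolution by
im2col + BLAS matmul and fixed-weight bilinear upsampling. Every kernel is
deterministic and all randomness flows from one integer seed, so loss
trajectories are exactly reproducible and the freeze contract is asserted
bitwise. Optimization is AdamW (lr 3·10⁻⁴, weight decay 10⁻², batch 8)
with cosine annealing over 200 epochs at full scale; the desk-scale
preset uses 20 epochs, batch 4, 64-px inputs, 2 transformer layers,
2 heads, base width 8.

## Design choices where the source design was open

- **Wavelet boundary handling** defaults to periodization: for orthonormal
  filters the transform is then an orthogonal map, so the energy added by
  enhancement satisfies ‖enhance(x)−x‖² = (λ₁−1)²‖LH‖² + (λ₂−1)²‖HL‖²
  exactly; half-sample symmetric padding (selectable) breaks this identity
  at the borders. Perfect reconstruction holds in all modes.
- **Subband naming** follows PyWavelets (LH = horizontal detail = highpass
  across rows), verified against a direct filter-bank computation. Since
  both directional bands are amplified with equal defaults, the output is
  independent of the labeling.
- **GPSA integration** has two plausible routes: multiplicative gating of
  the projected features and the additive logit bias. Both are
  implemented; the bias path (the one with explicit equations behind it)
  is the default, the gate sits behind a flag.
- **Mask-to-grid mapping**: masks meet feature maps by area-fraction
  pooling thresholded at 0.5. Lesions that vanish at the token grid fall
  back to uniform weights — a constant g makes the rank-1 bias row-constant,
  which softmax ignores, so the bias degrades gracefully to no-op — and
  are excluded from the attention supervision loss.
- **Gaussian weights are a detached guidance signal**: gradients flow into
  the learnable scale λ but not through G into the encoder, keeping the
  prior a prior.
- **Transfer scope**: the checkpoint's full state initializes the phase-2
  model, but only the venous-branch encoder is frozen; the non-contrast
  encoder, GPSA scale, transformer and decoder remain trainable. Phase 2
  refuses to run with an unfrozen venous encoder unless the ablation mode
  overrides it.
- **Soft Dice** uses probability sums with a 10⁻⁶ smoothing constant, which
  defines the empty-truth/empty-prediction case as loss 0.
- **Attention supervision** compares each query's softmaxed attention row
  (head-mean, final layer) to the binary token target via clamped BCE,
  averaged over queries; it is active in phase 2 only by default.
- **Metrics**: Hausdorff distance is the maximum (100th percentile)
  boundary-to-boundary Euclidean distance between pixel centres on 2-D
  slices, spacing-scaled (HD95 behind a flag), computed by exact Euclidean
  distance transforms; when either mask is empty it is reported missing.
  Dice/IoU/ACC are defined as 100% when truth and prediction are both
  empty. ACC is plain pixel accuracy over the whole frame. Case strata use
  the largest lesion's measured maximum diameter, with half-open intervals
  [0,10), [10,20), [20,∞) mm.
- **Split sizing** floors the later fractions and gives the remainder to
  the training split, so 654 cases at 80/10/10 yield 524/65/65.

## The phantom: what it emulates and what it does not

The generator produces paired 64-px (desk preset) or 512-px slices:
textured uniform parenchyma (60 HU, smoothed texture sd 5 HU), elliptical
lesions with random eccentricity in [1.0, 1.8], phase-dependent lesion
contrast (−40 HU venous, −12 HU non-contrast — free parameters chosen so
non-contrast lesions are visible but low-contrast, surfaced in config),
and independent per-phase additive noise (sd 8 HU). Lesion diameters
follow a truncated normal (mean 24.6 mm, sd 18.3 mm, range 3.2–87.5 mm at
full scale; rescaled to (16, 8, [3.2, 30]) mm in the 48-mm desk field of
view so all three size strata still occur). The recorded lesion diameter
is measured on the rasterized mask, as lesion size is read off a scan.

The phantom deliberately omits liver shape, vessels, neighbouring organs,
partial-volume blur and scanner artifacts. Passing tests on it show that
the pipeline's mechanics — enhancement, biased attention, transfer,
optimization, metrics — behave as specified under the stated intensity
model; they do not certify segmentation quality on clinical CT.

## Problem sizes used in the shipped studies

The test-suite and the reproduction script run the two-phase protocol at
desk scale: 200 phantom cases split 80/10/10, 20 + 20 epochs, three seeds,
judged against an untrained same-architecture baseline on held-out cases.
The ablation harness runs all eight {transfer, GPSA, WEEM} combinations at
a reduced size (tens of cases, short schedules) to verify the design runs
to completion and that disabled components are bypassed (asserted by call
counters), not merely neutralized. The wavelet sweep uses a deterministic
boundary-contrast proxy (mean squared gradient in a band around the lesion
boundary) by default; the train-and-evaluate scorer is available behind a
flag.

## Known limitations

- The intensity model is piecewise-constant plus noise; enhancement gains
  measured on it overstate what smooth-edged clinical lesions would show.
- Population Gaussian statistics assume the training and test feature
  distributions match; domain shift between real scanners is not modelled.
- The desk-scale network (≈10⁵ parameters) is far below the full-scale
  configuration; absolute Dice values on the phantom are not comparable to
  clinical benchmarks.
- 3-D support is a thin stack mode for resampling/distance tests only; the
  network is strictly 2-D.
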