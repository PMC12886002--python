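# hemaseg

Segmentation of liver hemangiomas in **non-contrast CT** by transferring
what a model can learn from contrast-enhanced (portal-venous-phase)
imaging. Hemangiomas are conspicuous when contrast agent is on board and
subtle without it; contrast agents, however, are contraindicated for
patients with allergies or renal insufficiency. This package implements
and tests a cross-phase pipeline for that setting, aimed at researchers in
medical image analysis who want a fully deterministic, CPU-sized,
inspectable implementation of each ingredient.

## The method

Three components wrap a hybrid CNN–transformer encoder–decoder:

- **Wavelet edge enhancement.** A one-level 2-D DWT splits each
  normalized slice into subbands LL/LH/HL/HH; the directional detail
  bands are amplified, `LH* = λ₁·LH`, `HL* = λ₂·HL` (defaults sym4,
  λ₁ = λ₂ = 2.0), and the slice is reconstructed by the inverse
  transform, sharpening lesion boundaries while leaving the approximation
  band (anatomy) and the diagonal band (noise) untouched.
- **Gaussian position-sensitive attention.** Tumor-region feature
  statistics μ, σ define multi-scale Gaussian weights
  `G = ⅓ Σ_k exp(−(I−μ)² / (2(kσ)² + ε))`, k ∈ {0.5, 1, 2}, ε = 10⁻⁵.
  Flattened into `g`, they bias every self-attention layer additively:
  `A = QKᵀ/√d_k + λ·ggᵀ` with λ learnable (init 0.5). A BCE supervision
  term ties attention rows to the token-level tumor target:
  `L_total = L_Dice + α·L_attention`, α = 0.3. At inference the per-case
  statistics are replaced by population averages learned in training.
- **Pre-train / freeze / transfer.** The model is first trained on
  venous-phase images with soft Dice loss; the venous-branch encoder is
  then frozen and the remaining modules adapt on paired non-contrast
  data.

Because paired clinical CT of this kind is not publicly distributable,
the package ships a **paired-phase phantom generator**: geometrically
identical HU-valued phases with elliptical lesions (truncated-normal
diameters, mean 24.6 mm, sd 18.3 mm, range 3.2–87.5 mm at full scale),
strong lesion contrast in the venous phase (−40 HU) and weak contrast
without agent (−12 HU), 0.75 × 0.75 mm pixels, and size strata
Tiny < 10 mm, Small [10, 20) mm, Big ≥ 20 mm. All experiments in the
test-suite run on this phantom at desk scale (64-px slices, ~10⁵-parameter
model) on a single CPU.

## Worked example

```python
import numpy as np
from hemaseg import phantom, training, evaluation

cfg = phantom.PhantomConfig.tiny(seed=0)            # 64-px paired phantom
splits = phantom.generate_dataset(cfg, 200, seed=0) # 160 / 20 / 20 cases

# pretrain on venous -> freeze encoder -> adapt on non-contrast
pipeline = training.run_protocol(splits["train"], seed=0)

report = evaluation.evaluate_model(pipeline, splits["test"])
print(f"Dice {report.dice:.1f}%  IoU {report.iou:.1f}%  "
      f"ACC {report.acc:.1f}%  HD {report.hd_mm:.2f} mm")
print(report.per_stratum)
```

On one CPU this runs in a few minutes and prints

```
Dice 47.0%  IoU 38.1%  ACC 97.0%  HD 4.39 mm
{'Tiny': 0.0, 'Small': 52.8284113770205, 'Big': 84.2839456160347}
```

i.e. the adapted model recovers large lesions well on held-out
non-contrast phantom slices, with the familiar pattern that tiny lesions
are hardest (here missed entirely at this model size and seed); pixel
accuracy is high simply because lesions occupy few pixels. Numbers are
for the desk-scale phantom and vary seed to seed (seed 1 reaches 72.5%
Dice); they say nothing about clinical CT — see `docs/methods.md` for
what the phantom does and does not emulate.

The command-line interface exposes the same steps:

```bash
hemaseg generate --n-cases 10 --seed 1 --out data/        # NIfTI + manifest
hemaseg enhance data/train/case_0000_noncontrast.nii.gz enhanced.nii.gz
hemaseg sweep --wavelets sym2,sym4,db4 --grid 1.3:2.2:0.1 --out sweep.csv
hemaseg pretrain --n-cases 50 --out ckpt/venous.npz
hemaseg transfer-train --pretrained ckpt/venous.npz --out ckpt/final.npz
hemaseg evaluate --model ckpt/final.npz --out report.csv
hemaseg ablate --out ablation.csv                         # 8 flag combinations
hemaseg describe                                          # shape table
```

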