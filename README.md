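# dentomorph

Bio-inspired imputation and desk-scale diffusion for dental images.

Pediatric dental images often arrive with missing or corrupted pixel regions,
and generic inpainting ignores two things a pediatric dentist cannot: gum
tissue is continuous and structurally supportive, and dentition changes
systematically with developmental stage (primary → mixed → permanent, ages
2–14). `dentomorph` implements two imputation operators built around those
observations, usable standalone or as loss terms inside a small
denoising-diffusion trainer, plus the evaluation metrics and published-table
statistics that go with them.

## The operators

**GAPI (Gum-Adaptive Pixel Imputation).** A masked pixel is filled from its
known 8-connected neighbors with normalized weights

```
W(p_i) = α·S(p_i) + β·C(p_i, p_t) + γ·T(p_i)
```

where `S = ‖∇I(p_i)‖ · max(0, cos θ)` is structural significance (Sobel
gradient magnitude times the cosine of the angle between the gradient and the
direction toward the target, clamped at zero), `C` is a continuity factor
(Gaussian affinity of the neighbor intensity to the neighborhood mean, scaled
by 1 for axial and 1/√2 for diagonal neighbors), and `T` is a tissue
compatibility score (1 for neighbors sharing the modal class around the
target, `τ` otherwise). Holes are filled boundary-inward (onion-peel order).
The matching loss scores a reconstruction by salience-weighted squared error
plus a structural term over 8-adjacent intensity differences.

**DTBR (Deciduous Transition-Based Reconstruction).** A transition
probability model `p(value bin | stage, region class, context bin)` is built
from labeled exemplars, and a masked pixel is filled with the conditional
expectation `Î(p) = Σ_k p_k v_k` over value-bin centers, conditioned on the
patient's developmental stage (from age metadata or morphology-based
classification). The matching loss is region-weighted squared error plus a
stage-consistency term over per-region transition features.

**Diffusion trainer.** A small convolutional ε-predictor is trained under a
squared-cosine noise schedule with the composite objective
`L = L_diffusion + λ_GAPI·L_GAPI + λ_DTBR·L_DTBR` (defaults λ_GAPI = 0.8,
λ_DTBR = 0.6), AdamW, EMA, warmup, and gradient accumulation — all in numpy
with analytic gradients. Inpainting runs the learned reverse chain while
re-imposing known pixels at every step.

Everything is exercised on synthetic dental phantoms (stage-parameterized
tooth arches with ground-truth class maps), so no data downloads are needed.

## Worked example

```python
import numpy as np
import dentomorph as dm

# a stage-3 (early mixed dentition) phantom with 20% blob corruption
phantom = dm.generate_phantom(stage=3, size=(64, 64), seed=7, noise_sd=0.0)
corrupted, cmask = dm.corrupt(phantom.pixels, "blobs", 0.2, seed=1)

restored = dm.gapi_impute(corrupted, cmask.mask, phantom.class_map)
print(f"masked fraction : {cmask.fraction:.3f}")
print(f"SSIM corrupted  : {dm.ssim(corrupted, phantom.pixels):.3f}")
print(f"SSIM restored   : {dm.ssim(restored, phantom.pixels):.3f}")
```

prints

```
masked fraction : 0.200
SSIM corrupted  : 0.643
SSIM restored   : 0.941
```

i.e. a fifth of the image was knocked out (SSIM against the clean phantom
drops to 0.643 with zero-filled holes) and GAPI's neighborhood-weighted fill
brings structural similarity back to 0.941.

The same operators run from the shell:

```bash
dentomorph phantoms --stage 3 --count 10 --seed 1 --out phantoms/
dentomorph corrupt --image phantoms/phantom_s3_0000.png --fraction 0.2 --out c/
dentomorph impute --image c/phantom_s3_0000_corrupted.png \
    --mask c/phantom_s3_0000_mask.npz --method gapi --out restored/
dentomorph paper-tables --out tables/
```

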