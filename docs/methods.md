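# Methods

This note documents the models implemented in `dentomorph`, the choices made
where the design was genuinely open, and what the synthetic experiments do and
do not show.

## Synthetic dental phantoms

The phantom generator is the package's stand-in for clinical dental imagery:
a parabolic arch of bright elliptical teeth (intensity 0.9), a gum band of
intermediate intensity (0.5) along the arch, dark background (0.15), optional
additive Gaussian noise (default sd 0.02, clipped to [0,1]), and a noise-free
ground-truth class map. Developmental stages 1–6 cover ages 24–168 months in
left-closed 24-month brackets (early primary dentition through the maturation
phase of the permanent dentition).

The stage → morphology table (`STAGE_MORPHOLOGY`) fixes, per stage, the
nominal tooth count, relative tooth size, the fraction of positions left
empty (erupting/exfoliated teeth), and the fraction of teeth drawn
half-erupted. The number of missing teeth is `round(fraction · n)`, so the
*rendered* tooth count is deterministic per stage — 7, 8, 9, 10, 11, 12 for
stages 1–6 — while gap positions and eruption states remain seeded-random.
This makes stage monotonicity a property of the table rather than of sampling
luck, and gives the stage classifier a clean morphological signal. Missing-
pixel corruption comes in three flavors: i.i.d. Bernoulli, thresholded
Gaussian random fields ("blobs", fraction matched by the field quantile), and
greedy random rectangles. Masked pixels carry a sentinel 0 plus an explicit
boolean mask; imputers consult only the mask.

What the phantom deliberately does **not** emulate: radiographic acquisition
physics, per-tooth anatomy (crowns/roots), soft-tissue texture, 3D geometry,
or pathology. Passing tests therefore demonstrate algorithmic correctness and
relative behavior (e.g. GAPI beats mean-fill, stages are recoverable), not
clinical performance on real radiographs.

## GAPI

Raw neighbor weights are `α·S + β·C + γ·T` over the known members of the
8-connected neighborhood, normalized to sum to one; if all raw weights vanish
(flat region with γ = 0) the weights fall back to uniform.

- **S, structural significance** = Sobel gradient magnitude at the neighbor
  times the cosine between the gradient and the direction to the target,
  clamped below at 0: negative alignment means the edge points away from the
  hole and should not attract weight. Gradients use 3×3 Sobel stencils with
  reflective (edge-duplicating) padding and are recomputed at every peel so
  freshly imputed pixels inform later ones.
- **C, continuity** = `exp(−(I(p_i) − m_N)² / 2σ_c²) · s`, where `m_N` is the
  mean of the target's known neighbors and `s` is 1 for axial, 1/√2 for
  diagonal neighbors. The underlying formulation names intensity similarity
  and spatial consistency without formulas; this realizes them as a Gaussian
  affinity and an inverse-distance scale.
- **T, tissue compatibility** is 1 when the neighbor's class matches the
  modal class among the target's known neighbors, else `τ`; modal ties break
  by priority tooth > gum > background.

Defaults: α = 0.5, β = 0.3, γ = 0.2 (decreasing emphasis in listing order),
σ_c = 0.1, τ = 0.25. Scheduling is onion-peel: every masked pixel with at
least one known neighbor is imputed per peel, in descending known-neighbor
count with row-major tie-breaks; within a peel all reads come from the
peel-start snapshot, so results are order-independent and fully
deterministic. Each fill is a convex combination of known intensities, so
imputed values never leave the dynamic range of the hole boundary.

The GAPI loss is `mean_p w_p (v_p − v̂_p)² + λ_structure · mean_{(p,q)}
w(p,q) (R − R̂)²` over 8-adjacent pairs, with `R(p,q) = I(p) − I(q)`,
`w(p,q) = (w_p + w_q)/2`, and per-pixel salience `w_p` the gradient magnitude
of the original max-normalized to [0,1] (uniform on flat images). The pair
and pixel sums are averaged over their counts so λ tuning is
resolution-independent. Salience, the pair weights, and the mean
normalization are this package's choices; the source formulation leaves
`w_p`, `R`, and `w(p,q)` undefined.

## DTBR

The transition model is a Laplace-smoothed conditional histogram
`p(value bin k | stage S, region class R, context bin)` with K = 16 value
bins and B = 8 context bins by default; the context of a pixel is the mean of
its 8 neighbors. Tooth *type* is collapsed into the 3-class region map
(background/gum/tooth): the phantom has no per-tooth identity, a documented
simplification. Stages absent from the exemplars are an error at
smoothing = 0 and a warned uniform row otherwise. Imputation shares the GAPI
peel schedule and fills each pixel with the conditional expectation of the
bin centers, using the mean of its known neighbors as context, so fills are
bounded by the first and last bin centers.

Stage classification prefers metadata: given an age it returns the age
bracket. Otherwise the image's features — tooth connected-component count
(4-connectivity), tooth area fraction, arch gap fraction — are matched to the
nearest per-stage centroid (features whitened by their pooled standard
deviation; ties to the lower stage). Centroids are built from labeled
phantoms.

The DTBR loss is `Σ_r D(r,S)·MSE(I_r, Î_r) + λ_temporal·Σ_r ‖T(I_r) −
T(Î_r)‖²` with transition features T = (mean intensity, mean Sobel gradient
magnitude, fraction above the tooth threshold) per region; empty regions
contribute zero. `D(r,S)` defaults to 1 except tooth rows at the
mixed-dentition stages 3–4, where transition emphasis is highest (weight 2);
λ_temporal defaults to 0.5. Both are configurable.

## Diffusion trainer

The forward process is the standard Gaussian chain with a squared-cosine
`ᾱ_t` schedule (offset s = 0.008, β clipped at 0.999). The training objective
is ε-prediction MSE — the source presents the forward and reverse kernels but
not an objective, and ε-MSE is the standard choice — plus the bio losses with
weights λ_GAPI = 0.8 and λ_DTBR = 0.6.

Implementation choices that matter:

- **Everything is numpy with analytic gradients.** The noise predictor is a
  three-layer 3×3 conv net (timestep embedded as four constant sinusoid
  channels) with hand-written im2col backprop; AdamW has decoupled weight
  decay (weights only, not biases) and linear warmup; dropout is inverted;
  the EMA shadow uses the warmup rule `decay_t = min(decay, (1+t)/(10+t))` so
  short runs are not anchored to the random initialization. Loss gradients
  (including the chain through the Sobel stencils of the edge-density
  feature, via the adjoint of reflect-padded correlation) are verified
  against central differences in the tests.
- **Bio losses act in image space on the clamped prediction.** The losses are
  defined over pixel intensities, so they are applied to
  `x̂_0 = (z_t − √(1−ᾱ_t) ε̂)/√ᾱ_t` clamped to [0,1] (zero gradient where
  clamped): without the clamp the 1/√ᾱ_t factor blows the image-space terms
  up at deep timesteps and swamps the ε objective. The foreground-fraction
  feature is piecewise constant; its (almost-everywhere zero) gradient is
  omitted.
- **Inpainting** runs the reverse chain with the schedule's posterior
  variance (Σ_θ is not learned) and re-imposes the known region at every step
  by forward-diffusing the observed pixels to the current noise level —
  mask-replacement conditioning. Reverse steps may be strided.
- **Desk profile.** Tests and the acceptance script run the
  `DiffusionConfig.desk()` profile: 32×32 pixel space (identity autoencoder),
  T = 200, learning rate 3e-3, warmup 20, EMA decay 0.99, gradient
  accumulation 4, batch 16; the smoke experiment trains 200 optimizer steps
  on 64 phantoms and evaluates inpainting on 30 corrupted phantoms with 50
  strided reverse steps. The paper-scale profile (T = 1000, 512×512, lr 1e-4,
  warmup 1000, EMA 0.9999, 100 epochs) remains the documented default of
  `DiffusionConfig` but is not exercised.
- **Toy autoencoder.** The latent-space option is a patchwise linear
  autoencoder: non-overlapping 8×8 patches projected onto their top-4
  principal components (closed-form MSE minimizer for a linear code), giving
  a 4-channel latent at 1/8 resolution — the same compression ratio as a
  512→64 4-channel VAE — with a phase-aware 5×5 linear deblocking filter
  (one ridge fit per within-block position) on the decoder. On noise-free
  64×64 phantoms the roundtrip reconstruction exceeds 25 dB PSNR. The trainer
  itself runs in pixel space by default; the autoencoder documents and tests
  the latent pathway.

## Metrics

PSNR is `10·log₁₀(MAX²/MSE)` with a +∞ sentinel for identical images. SSIM is
the standard luminance–contrast–structure product (11×11 Gaussian window,
σ = 1.5, c1 = (0.01L)², c2 = (0.03L)²) via scikit-image; the printed SSIM
formula in the source inverts the standard ratio and is treated as a
typographical slip. The Fréchet distance uses Gaussian moments with a
symmetrized matrix square root and small negative eigenvalues clamped at
zero. The inception-style score uses natural-log KL with the 0·log 0 = 0
convention and is bounded in [1, K]. Confusion-matrix rates report NaN for
zero denominators rather than 0.

There is no pretrained Inception network here: feature embeddings are
backend-parametric (fixed-seed random 3×3 convolution features with
mean/standard-deviation pooling, or a small logistic-regression stage
classifier whose softmax rows also feed the inception-style score).
Published absolute IS/FID values are therefore not comparable and not
targets; only relative comparisons within one backend are meaningful.

## Printed-table statistics

The bundled CSV fixtures transcribe the published class counts, the
generation-metric comparison, and the detector before/after table. Derived
statistics (descriptives, gap percentages, normalized rankings, improvement
means, paired/one-sample t) are recomputed from those inputs and compared
with the printed values at the printed rounding. Known irreproducibilities,
flagged in the discrepancy report and never asserted equal:

- the dataset SD 65.42 and variance 4,279.77 are inconsistent with the six
  printed class counts (sample SD 57.99);
- the SSIM column mean prints 0.918 but the column averages 0.916; the IS
  column SD prints 0.53 vs a sample SD of 0.52;
- the paired t for the mAP improvements prints 17.35, but the five printed
  differences give 28.43 by the standard formula (the other three t values
  disagree similarly);
- the "average normalized score" ranking is not reproducible under either
  min–max or ratio-to-best normalization for any non-top row (both methods
  are implemented and reported);
- gap percentages reproduce only when the reference is the two-decimal
  printed column mean (e.g. −34.8% for FID 4.21 vs 6.46; the full-precision
  mean 6.4645 gives −34.9%), so the recomputation uses printed-rounding
  references and records the convention.

## Numerical conventions and degenerate inputs

Intensities are [0,1] doubles throughout (8/16-bit integer scaling at the I/O
boundary). Bins are left-closed with the final bin right-closed. Weight
normalization makes imputed constants exact to one ulp. A fully masked image
is rejected ("no boundary information"); empty masks are identities;
zero-variance t statistics and zero-denominator rates return NaN markers.
All randomness flows from explicit integer seeds; regenerating any artifact
with the same parameters and seed is bit-identical.

## Known limitations

The phantom's schematic geometry cannot validate clinical claims; the
transition model conditions on 3 region classes rather than per-tooth
identity; the desk-scale trainer demonstrates mechanism (loss decrease,
conditioning, ablation degeneracy) rather than generation quality; and FID/IS
backends are desk-scale surrogates for learned perceptual embeddings.
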