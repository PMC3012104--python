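# Methods

## The model

`ctxsal` scores visual saliency as the improbability of a *target* patch
given its co-occurring *context* under the statistics of an ensemble of
natural scenes. For still images the target is the patch inside a circular
center and the context is the annular surround; for movies the target is
the current frame of a small spatiotemporal volume and the context is the
preceding frames.

The generative assumption is a block-triangular linear source model for the
whitened target/context pair (z_c, z_s):

    z_s = A_ss s_s
    z_c = A_cs s_s + A_cu s_u

with the context sources s_s and the unpaired target sources s_u mutually
independent, sparse and heavy-tailed. Columns of A_cs are the *paired*
target components — continuations of context structure into the target
(an oriented edge crossing the center/surround boundary, a translating
texture). Columns of A_cu are the *unpaired* components: target structure
the context carries no information about. By Bayes' rule the conditional
density of a target given its context then factorizes over the unpaired
amplitudes u = s_u alone; everything context-mediated cancels.

Each unpaired amplitude is modeled with a generalized Gaussian
p(u) = β/(2sΓ(1/β))·exp(−(|u|/s)^β), which for natural-scene components is
sharply peaked at zero with long tails (β well below 2). Saliency is the
log-ratio of the most likely target's conditional density to the observed
one. Because every component density is unimodal at zero, the maximizing
target sits at u = 0 independently of the context, and the measure has the
closed form

    S(u) = Σ_i (|u_i| / s_i)^{β_i}   (nats, ≥ 0, = 0 iff u = 0).

Computing a saliency map therefore needs exactly one linear filter
application per window plus this elementwise formula — no per-image
statistics, no normalization, no optimization.

## Fitting

The paper-level description ("modified FastICA") leaves the estimator open;
the package uses a staged procedure that enforces the triangular structure
by construction:

1. PCA-whiten the context patches (separately from the target, matching the
   separately reported dimensionalities) and run kurtosis-contrast FastICA
   (symmetric decorrelation, fixed-point iteration, tolerance 1e-6, max 500
   iterations, seeded random orthonormal initialization) → context sources.
2. Ordinary least squares of the whitened target on the context sources →
   paired loadings A_cs.
3. Whiten the regression residual and run FastICA again → unpaired sources
   and A_cu (columns unit-norm, sign fixed by the largest loading, ordered
   by decreasing |kurtosis|).
4. Compose stages into one filter W_u_joint on the concatenated whitened
   pair, so amplitudes are a single matrix–vector product at score time.

Between-group independence is *measured* (max cross-correlation between
recovered source groups, reported in the diagnostics), not assumed. On
pairs generated from the fitted model's own mixing blocks, amplitude
recovery and context-cancellation are algebraic identities (errors at
machine precision); on data from an independent planted model they are
limited by the O(n^(−1/2)) sampling error of the least-squares stage.

GG parameters are fitted per component by moment matching —
(E|u|)²/E[u²] = Γ(2/β)²/(Γ(1/β)Γ(3/β)) solved by bracketed root finding on
β ∈ [0.1, 10], then s from the variance — on amplitudes pooled over all
training patches (ensemble statistics, not per-image statistics). An
optional maximum-likelihood polish is available but off by default; the
moment estimator is already within a few percent at the sample sizes used.

## Mask geometry

A pixel belongs to the center iff its Euclidean distance from the central
pixel is ≤ (D−1)/2. This reproduces the reference dimensionalities exactly:
149/1368 values for grey 15/45 windows, 87/1044 for three-channel 7/23
windows, and 363/1089 for 11×11×4 color video volumes (current frame as
target, three preceding frames as context). Vectorization is channel-major
with video context frames stacked oldest first; an explicit-radii override
exists for non-standard conventions.

## Maps and evaluation

Maps are computed for every window center on a stride grid, valid-only (no
padding); the map records its offset and stride so scene-coordinate
fixations can be assigned to the nearest scored window. The map of record
is raw — no smoothing, no normalization; renderings for inspection are
separate, monotone 8-bit images.

Evaluation controls for the central tendency of gaze by the shuffled
protocol: control locations are fixation coordinates borrowed from *other*
scenes. AUC is the midrank Mann–Whitney statistic (identical to a dense
threshold sweep under the half-tie convention — both are implemented and
agree to 1e-12). KL divergence uses 100 equal-width bins spanning the
pooled score range with additive smoothing 1/(total count); neither bin
count nor smoothing is reference-prescribed, so both are explicit,
overridable parameters. Standard errors come from a seeded nonparametric
bootstrap over scenes (1000 resamples).

## Synthetic study conditions

All tests run on synthetic data; the generators define the conditions.

* **Planted source model** — default Laplace sources (GG β = 1), the
  heavy-tailed regime where kurtosis ICA is well identified; recovery runs
  use d_c=12, d_s=16, k_s=8, k_u=4, n=5·10⁴.
* **Texture scenes** (static toy ensemble) — a jittered 12-px grid of 9-px
  Gabor elements whose orientations follow a smooth global field with 10%
  outliers, amplitudes uniform in ±[0.25, 0.45]. The static toy model uses
  7/31 windows so the surround annulus actually covers neighboring
  elements — without that, orientation context does not exist and
  orientation pop-out is inexpressible. Scene base orientations are
  stratified over [0, π) so the ensemble is orientation-balanced: a model
  trained on a lopsided orientation diet cannot judge orientation
  contrast. Conditions: k_c=20, k_s=50, k_u=15, 25k patches from twelve
  128×128 scenes.
* **Drifting sequences** (video toy ensemble) — the same textures
  translating rigidly at ≤1 px/frame: a mostly-static world in which faster
  motion is the salient deviation. Training patches are mirror-augmented
  (exact left-right/up-down flips) so the fitted filters respond
  symmetrically to symmetric stimuli rather than inheriting sampling
  asymmetries. Conditions: 11×11 windows, temporal depth 2, k=25/25/25,
  20k patches before augmentation.
* **Pop-out arrays, moving dots, anomaly scenes** — rendered analytically
  with ground-truth locations; element size and pitch match the training
  textures so the background is in-distribution and only the singleton is
  anomalous.
* **Synthetic observers** — fixations sampled proportionally to a map's
  scores. "Unrelated" observers are driven by maps of held-out scenes, not
  by a permutation within the evaluated pool: a within-pool reassignment
  leaks own-map-proportional coordinates into the shuffled negative pool
  and biases the null AUC below 0.5.

What these fixtures do **not** show: performance on natural images (no
1/f spectra, occlusion, lighting or semantic content), color-opponent
statistics, or real human gaze with its oculomotor biases. Passing tests
demonstrate the estimator's correctness and the mechanism of
context-mediated pop-out, not gaze-prediction accuracy on photographs; the
reference evaluations on public gaze datasets require those corpora and are
deliberately outside the test suite.

## Numerical choices and degenerate inputs

* Whitening retains the top-k principal components by decreasing variance
  and refuses k beyond the numerical rank (reporting the achievable rank);
  constant directions carry zero variance and are never selected.
* FastICA raises on non-whitened input (covariance deviation > 1e-3) and
  flags non-identifiable (near-Gaussian) sources via near-zero kurtosis
  diagnostics instead of failing.
* GG fitting requires ≥100 samples and nonzero variance; moment ratios
  outside the achievable range clamp the shape to the [0.1, 10] bracket
  with a warning.
* Log-luminance uses ln(v + ε), ε = 1/255 by default — defined at zero,
  approximately one 8-bit quantization step. Block averaging precedes the
  log transform in the preprocessing pipeline; the operations do not
  commute.
* Constant scenes yield identical scores at every window (zero scores when
  the scene sits at the training mean); all-equal score sets give AUC 0.5
  and KL 0 by the tie/degenerate-range conventions.
* Maps persist as plain float CSV (format of record) plus an 8-bit PNG
  rendering; models as a versioned .npz container with a bit-exact
  round trip.

## Known limitations

* The estimator is linear throughout; contrast-normalization and other
  nonlinear context effects are out of scope.
* k_u defaults to k_c, but the toy static model retains 15 of 20 target
  dimensions; heavily truncated unpaired bases can produce spatially uneven
  sensitivity (visible as argmax offsets on point stimuli) — mitigated here
  by mirror augmentation and by keeping k_u close to k_c.
* Orientation pop-out exhibits saliency spillover: the singleton corrupts
  the *context* of its immediate neighbors, so windows ~one element pitch
  away also score high, and at some training seeds the global argmax lands
  on such a neighbor rather than on the singleton itself (the singleton
  still scores above ~99.9% of map locations). The pop-out canvas is fully
  tiled with elements so that only the singleton — not the array
  boundary — is anomalous.
* The bootstrap-over-scenes SE understates uncertainty when very few scenes
  carry most of the signal; evaluation fixtures use ≥10 scenes.
* The color 17/51 window configuration reported for one reference figure is
  not reproducible by the default mask rule; use `explicit_radii` if that
  convention is ever pinned down.
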