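# Methods

## Scope and data model

The package analyses the accuracy of threshold-based canopy photography for
leaf area index (LAI) estimation. No field imagery ships with it: every
input is either user-supplied (grayscale images; long tables of replicated
LAI estimates) or generated by the synthetic module, which is first-class,
tested code. One bundled text fixture — a 12-entity reference precision
table for broad-leaved trees — supports the aggregation stage without any
simulation.

## Boolean canopy scenes

Artificial canopies are Boolean models: discs of fixed radius with centres
uniform over the raster, overlap allowed, stamped sequentially until the
vegetation fraction (counted exactly from the mask, never estimated)
reaches the target cover. Boundaries are periodic, so the Boolean density
relation `cover = 1 − exp(−n·a/A)` (n discs of pixel area a on area A)
holds without edge bias; the tests check the disc count against this closed
form over repeated seeds.

Parameters and defaults:

* `circle_radius` = 10 px on a 1200 × 1200 px working raster — the
  "many small discs" regime of a printed sheet of 3 mm discs; both
  configurable.
* `cover_tolerance` = 0.005. Generation stops at the first crossing of the
  target, so the overshoot is at most one disc's cover contribution
  (~2·10⁻⁴ at the defaults); a radius too large to control cover to the
  tolerance raises rather than returning a silently biased scene.
* Every stochastic operation takes an explicit integer seed; there is no
  global random state, and regeneration with the same spec is
  bit-identical.

## Acquisition model

A binary scene is rendered to 8-bit grayscale by (in order): class mean
intensities (foliage 40, sky 220), Gaussian blur (σ = 1.5 px) creating the
mixed boundary pixels that make threshold choice ambiguous, radial
vignetting (strength 0.15, quadratic in distance from the optical centre),
additive Gaussian noise (SD 8), then rounding and clamping to [0, 255].
This is the package's own stand-in for print/photograph/lighting effects:
it reproduces the phenomenon that matters for the analysis — a bimodal
intensity histogram with an ambiguous valley — not any specific camera.
It does not model fisheye optical distortion, exposure error, chromatic
information (no RGB), or spatially structured illumination beyond
vignetting; conclusions from passing tests are therefore about
threshold-and-inversion behaviour under mixed-pixel ambiguity, not about
any particular sensor.

## Segmentation and inversion

Thresholds are integers T ∈ [1, 255]. The **sky** convention labels
intensity ≥ T as sky; the **green** convention labels intensity ≤ T as
vegetation. With equal T the two differ only on pixels exactly at T. The
auto threshold is Otsu's criterion, implemented as a vectorized scan of all
255 split points (the exact argmax under the package's split convention;
ties go to the smallest T); an `auto_bias` δ shifts it down for the sky
method and up for the green method, modelling users who anchor on opposite
pixel categories. δ = 6 grey levels is the method-effect experiment's
default — a tunable mechanism, not a hard-coded conclusion; with δ > 0 the
green method classifies more of the blurred boundary as vegetation and so
reports systematically higher cover and LAI.

Inversion uses the Poisson gap-fraction model. Flat view:
`LAI = −ln(1 − cover)` (extinction term G/cosθ taken as 1 at nadir).
Fisheye view (equidistant projection, zenith ∝ radius): the zenith range is
split into equal-width annuli (default 6 rings over 0–60°), and L is the
weighted least-squares solution of `ln P₀(θᵢ) = −G·L/cosθᵢ` through the
origin, weighted by ring pixel counts, with G = 0.5 (spherical leaf angle
distribution). A ring with zero gap is floored at one sky pixel before the
log and the estimate flagged `clamped`; if every ring is saturated the
estimate is additionally flagged unreliable. The result is an *effective*
LAI: no clumping correction and no species-specific leaf angle
distribution.

Trueness references use the same transform: reference LAI is
`−ln(1 − achieved_cover)`. Using one inversion on both sides makes the
agreement metrics insensitive to the choice of inversion to first order;
metrics are reported on both the LAI and the cover scale.

## ISO 5725 precision protocol

For each entity (a balanced p × n laboratory × replicate matrix, default
4 × 4):

1. **Cochran's test** on within-laboratory variances,
   `C = S²_max / Σ S²ᵢ`, targeting the largest-variance laboratory;
2. **Grubbs' test** on the laboratory means retained after Cochran,
   `G = |suspect − x̄| / S` with S the sample SD of the means, testing both
   extremes and reporting the larger deviation (ties to the maximum side).

Each test runs once (no iterative re-testing). A statistic above its 1%
critical value makes the laboratory an **outlier** (excluded); above the 5%
but not the 1% value, a **straggler** (flagged, retained). Critical values:
Grubbs via the closed Student-t form
`G = ((p−1)/√p)·√(t²/(p−2+t²))`, `t = t₁₋α/(2p), p−2`; Cochran from an
embedded classical table for small balanced designs with the F-quantile
formula `C = [1 + (p−1)/F₁₋α/p(ν, (p−1)ν)]⁻¹` as fallback — the two routes
agree to three decimals on the tabulated range (checked in the tests).
Degenerate inputs (all variances zero; all means equal) make a test "not
possible": nothing is flagged.

Variance components over the retained laboratories are the one-way
random-effects estimators: `S_r²` = pooled within-laboratory variance,
`S_L² = max(0, S_d² − S_r²/n)` from the variance of laboratory means, and
`S_R² = S_r² + S_L²` (the truncation at zero keeps `S_R ≥ S_r`). Limits are
`r = √2·t·S_r` and `R = √2·t·S_R` with t = 1.959964, the two-tailed 95%
normal quantile ("infinite degrees of freedom"); the factor ≈ 2.7718 is
exposed in the fit interface. If rounding of inputs ever makes r exceed R,
R is floored at r. Relative forms are 100·S/mean in percent.

Stratified aggregates take arithmetic means of r and R over a stratum's
entities; *relative* aggregates average the per-entity ratios
100·limit/mean (not the ratio of stratum means — the two differ, and the
per-entity convention is the one under which the bundled reference table's
printed class aggregates, e.g. 28.5% for the plantation-row class,
reproduce exactly). LAI-range strata use strict bounds (mean > 5,
mean < 1.5, 2.5 < mean < 4); entities between ranges belong to no LAI
stratum. Unbalanced matrices are rejected — the protocol here covers the
balanced design only.

The model surface follows the statsmodels convention:
`InterlabPrecision(matrices)` or `.from_dataframe(long_df)` builds the
model; `.fit()` returns `InterlabPrecisionResults` carrying per-entity
results, outlier reports, a printable `summary()`, and `stratify()`.

## Generative counterparts

`simulate_estimate_matrix` draws `value[l,k] = μ + B_l + e_lk` with
`B_l ~ N(0, σ²_between)` and `e_lk ~ N(0, σ²_within)`, truncated at zero
(LAI is non-negative). These are exactly the components the ISO analysis
estimates, so parameter recovery is a meaningful end-to-end check
(`S_r → σ_within`, `S_R → √(σ²_within + σ²_between)`). Defaults
σ_within = 0.2, σ_between = 0.1 LAI units put the simulated relative
precision in the range observed for real broad-leaved canopies.
`simulate_user_thresholds` is the image-route analogue: a per-user
systematic offset (SD 10 grey levels) plus per-session wobble (SD 3)
around the optimal threshold, clamped to [1, 254]. The truncation at zero
makes both generators slightly non-Gaussian near zero means; with the
default parameters and the study's LAI levels the effect is negligible.

## Experiments and problem sizes

* **Trueness replication** — 14 cover levels evenly spaced over
  [0.30, 0.85], one 1200² scene per level, 4 replicate acquisitions,
  sky-method auto threshold (no bias), flat inversion on both sides. Runs
  in a few seconds; reported as R² and RRMSE between replicate-mean and
  reference LAI. In the noise-free limit (no blur, noise or vignetting)
  thresholding is exact and both metrics are exact (R² = 1, RRMSE = 0).
* **Method effect** — 60 scenes over the same cover range, each segmented
  with both conventions at Otsu ± 6; paired t-test on green − sky LAI.
* **Precision replication** — 12 entities (three canopy classes × four LAI
  levels, means taken from the reference table) in the fast
  variance-component mode, or a mechanistic image mode (smaller scenes,
  default 400², where each laboratory's threshold comes from the user
  model and every replicate is re-rendered and re-segmented). In the image
  mode high-LAI levels saturate a flat view (cover is capped at 0.90,
  i.e. LAI ≈ 2.3), so it is used for mechanism studies — e.g. the
  between-user threshold bias inflating R — not for reproducing high-LAI
  rows.

Test-suite simulation sizes (50-seed disc-count checks at 300², 100-scene
method-direction checks at 300², 500-entity recovery runs) were chosen so
the whole suite runs in about a minute while keeping Monte-Carlo standard
errors well inside the asserted tolerances.

## Known limitations

* The screening stage implements the single-outlier Cochran and Grubbs
  tests only (no double-Grubbs, no robust ISO 5725-5 alternatives). With
  p = 4 laboratories the single-Grubbs statistic is bounded by
  (p−1)/√p = 1.5 while its 1% critical value is 1.496, so the test's power
  to *exclude* a deviant laboratory is intrinsically modest at this design
  size even for large shifts; Cochran detection of a 100× variance
  inflation at the 1% level is likewise capped near 95% by the heavy tail
  of F(9, 3). These are properties of the protocol at p = 4, not of the
  implementation.
* Flat-view inversion saturates as cover → 1; the fisheye route spreads the
  information over zenith rings but still carries the zero-gap clamp.
* The acquisition model's noise is pixel-independent; real images have
  structured noise (JPEG artefacts, demosaicing, within-canopy radiance
  gradients) that can bias Otsu differently.
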