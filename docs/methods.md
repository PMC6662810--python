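# Methods

## Problem setting

Two groups of bone-slice micrographs are to be told apart: controls with a
fine, dense trabecular network, and an estrogen-deficient group whose
network is coarser and sparser.  At low magnification (whole-slice field
of view) the texture is blurry, so single-offset texture statistics are
unreliable; the pipeline therefore (a) measures texture in all four
raster directions and collapses them with data-driven weights, (b) fuses
texture with per-trabecula shape descriptors, and (c) prunes the fused
feature vector with a sparsity-inducing convex model before a linear SVM
is evaluated by leave-one-out cross-validation (LOOCV).

## Texture parameters

Images are quantized to G gray levels by uniform binning of [0, 255]
(default **G = 64**; low-power micrographs use little of the 8-bit range,
and 6-bit quantization is the customary reduction for co-occurrence
work).  No intensity normalization is applied before binning.

The co-occurrence matrix (GLCM) at pixel distance d and direction
θ ∈ {0°, 45°, 90°, 135°} counts ordered gray-level pairs in both
directions (symmetric) and is normalized to sum 1.  Coordinates are
(row, col) with row 0 at the top, so 45° means up-right.  Offsets:
0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0), 135° → (−d, −d).  With an
ROI mask, pairs with either pixel outside are dropped.  Eleven parameters
follow the Haralick definitions in the naming used by the MaZda texture
package: angular second moment, contrast, correlation, variance
(sum-of-squares), sum of variance (sum variance), mean sum (sum average),
entropy, sum entropy, entropy difference (difference entropy), residual
variance (difference variance) and inverse difference moment.  All
entropies use the natural logarithm with 0·log 0 ≡ 0.  On a
zero-variance image the correlation is undefined and is reported as NaN
with a warning — never silently coerced to a number.

The run-length matrix (GLRLM) counts maximal same-level runs per
direction; masked-out pixels break runs, and every in-mask pixel belongs
to exactly one run per direction.  Four statistics are derived: short run
emphasis (1/N_r)ΣΣ R(g,r)/r², long run emphasis (1/N_r)ΣΣ R(g,r)·r²,
gray-level non-uniformity (1/N_r)Σ_g(Σ_r R)², and run-length
non-uniformity (1/N_r)Σ_r(Σ_g R)².

Texture is computed over the whole image; the ROI mask feeds only the
shape stage (the masks delineate individual trabeculae, while the texture
of interest is that of the whole low-power field).

## Direction weighting

Per sample i, the sentinel parameter of each matrix family supplies four
direction values x(i,1..4):

    x̄ᵢ = ¼ Σⱼ x(i,j)
    v(i,j) = |x(i,j) − x̄ᵢ| / x̄ᵢ
    w(i,j) = v(i,j) / Σⱼ v(i,j)

and every parameter p of that family is reduced to p̄ᵢ = Σⱼ w(i,j) p(i,j).
Defaults: **correlation** for the GLCM family (computed at distance
**d = 3**, the distance at which co-occurrence parameters stabilize on
blurry low-power images) and **long run emphasis** for the GLRLM family —
the empirically most direction-sensitive parameter of each family.  One
weight vector is derived per sample per family (the per-sample reading of
the weighting equations), not a single global vector.

Degenerate cases fall back to uniform weights ¼ with a logged warning:
an isotropic sentinel (all v = 0), a zero sentinel mean, or an undefined
sentinel (NaN correlation on a constant image).  Uniform weights
reproduce plain direction averaging, which is also available directly as
the unweighted pipeline variants.

Direction sensitivity is quantified as the coefficient of variation
across the four directions (population SD / |mean|), averaged over
samples — the quantitative analog of judging fluctuation amplitude from
per-direction curves.  Distance stability scans d = 1..5 (configurable)
and recommends the smallest d from which on the relative change of every
monitored parameter (default: contrast, correlation, entropy, inverse
difference moment) between consecutive distances stays below 5%; if no
distance qualifies, the distance entering the step of minimal total
change is returned with a warning, ties resolved toward the largest d.

## Shape parameters

Connected components of the binary ROI mask (8-connectivity, minimum
area 20 px; holes kept) yield six dimensionless ratios:

* solidity = area / convex-hull area
* regional density = area / perimeter²
* correction rate = maximum inscribed-circle diameter / minimum
  enclosing-circle diameter
* convexity = convex-hull perimeter / perimeter
* roundness = area / (maximum Feret diameter)² — deliberately without
  the conventional 4/π factor, so a disk scores π/4 ≈ 0.785
* length–width ratio = long / short side of the minimum-area rotated
  bounding rectangle

and the seven Hu invariant moments of the binary silhouette (no log
transform; the downstream column standardization absorbs their scale).
Conventions: the perimeter is the Crofton 4-direction estimate (a traced
boundary polygon overestimates smooth digital outlines by ~6%, which
squares into a 12% bias of regional density; Crofton keeps the disk
ratios within ~1% of their analytic values); the convex hull and Feret
diameter come from the sub-pixel marching-squares contour; the inscribed
circle radius is the maximum of the Euclidean distance transform; the
enclosing circle is the exact minimum bounding circle of the contour.
Per-image aggregation is the area-weighted mean of component descriptors
(configurable: unweighted, largest-component).  "Regional density" is the
quantity sometimes called shape factor.

## Feature selection

The fused 28-feature matrix (columns standardized to mean 0, variance 1;
constant columns dropped with a warning) with labels Y ∈ {−1, +1}
(positive = disease group) enters

    min_b ‖Ab − Y‖₂² + ‖C₁∘b‖_F²/n₁ + ‖C₂∘b‖_F²/n₂ + λ₁‖b‖₁

where Cₖ is class block k minus its column means and ‖Cₖ∘b‖_F² =
Σⱼ Dₖ[j] bⱼ², Dₖ[j] the squared norm of column j of Cₖ.  The dispersion
terms penalize coefficients on features that scatter widely within a
class, so the retained support favors features that are simultaneously
predictive and internally consistent.  ±1 coding is the standard
least-squares classification surrogate.  Setting D₁ = D₂ = 0 gives the
ordinary Lasso baseline.

The solver is ISTA: b₀ = 0, step bₖ₊₁ = shrink(bₖ − ∇f(bₖ)/L, λ₁/L) with
L = λ_max(2AᵀA + (2/n₁)D₁ + (2/n₂)D₂), stopping when ‖bₖ₊₁ − bₖ‖₂ <
10⁻⁶ or after 10 000 iterations (then flagged unconverged with a
warning).  The proximal threshold is λ₁/L — the exact minimizer of the
quadratic surrogate; a `threshold_scale="absolute"` flag applies a raw
λ₁ threshold instead, for comparison with the shrinkage step sometimes
written without the 1/L scaling (the absolute variant is *not* the
proximal operator and solves a different fixed point: on the 1-feature
problem min 2(b−1)² + |b| it returns 0 where the true minimizer is
0.75).  The solver is wholly deterministic.  Support = coefficients with
|bⱼ| > 10⁻⁸.

**Penalty selection.**  When λ₁ is not supplied, the model solves a
30-point descending log grid from λ_max = 2‖AᵀY‖_∞ (the smallest penalty
with an all-zero solution) down to λ_max·10⁻³, warm-starting each solve
from the previous one (the objective is convex, so continuation affects
speed only), and picks the λ₁ minimizing the extended BIC

    n log(RSS/n) + k (log n + 2γ log p),   γ = 0.5

with k the support size — the standard EBIC setting for p of the same
order as n, which is selection-consistent for strong signals.
Prediction-driven rules were considered and rejected: with a strong
class contrast one or two features already saturate small-sample LOOCV
accuracy, so an accuracy score is massively tied and carries almost no
information about which support is correct (it either keeps nearly
everything or almost nothing, depending on the tie-break).  That rule
remains available as `select_lambda(method="accuracy")` (support capped
at 0.6p, ties toward smaller λ₁).  The final fit at the chosen λ₁
continues from the path iterate.

Selection runs once on the full dataset before LOOCV by default,
mirroring the historical protocol of this pipeline; `selection_scope=
"nested"` redoes selection inside every training fold and is the
statistically safer mode (the default optimistically biases the two
selection variants, which must be kept in mind when reading their
accuracies).

## Evaluation

Linear SVM, C = 1.0, features standardized with training-fold statistics
only; LOOCV confusion counts pooled over folds.  Positive class = the
disease group (OVX), so sensitivity is the detection rate.  Youden's
index J = SEN + SPE − 1.  Variants: TNS (plain-averaged texture), TSNS
(+shape), TYS (weighted texture), TSYS (+shape), TSYLS (Lasso-selected
TSYS), TSYLC (dispersion-selected TSYS).

## Synthetic data

`gen_trabecular_image` thresholds a smoothed Gaussian random field:
seeded white noise filtered at scale `correlation_length` (with a 1.6×
vertical anisotropy so the directional machinery has signal), thresholded
at the `fill_fraction` quantile into a trabecular mask, rendered bright
on dark with soft edges, blurred (`blur_sigma`, default 2 px, emulating
low-power optical blur) and corrupted with Gaussian pixel noise
(`noise_sd`, default 6 gray levels).  Class defaults encode the observed
direction of group differences: controls (SHAM) `correlation_length` 3 px
and `fill_fraction` 0.45 — finer, denser, texturally richer; the
osteoporotic model (OVX) 6 px and 0.28.  Default image size 512×512,
8-bit.  All generators are pure functions of (parameters, seed).

What this emulates: the relative texture statistics of the two groups
(higher entropy, contrast and non-uniformity in controls), per-strut
shape variation, optical blur and sensor noise.  What it does not:
staining variation, uneven illumination, slice-preparation artifacts,
anatomically realistic rod/plate architecture, or the hand-delineation
variability of real ROIs.  Passing tests therefore demonstrate that the
pipeline machinery is correct and that it detects this class of texture
contrast — not a clinical performance claim.  With the default contrast
the synthetic task is easy (LOOCV accuracy at or near 1.0), so the
variant comparison checks ordering, not absolute levels.

`gen_feature_matrix` builds labeled matrices with known ground truth:
informative columns Normal(±Δ/2, 1) by class, redundant columns copying a
random informative column plus Normal(0, 0.3) noise (emulating the strong
inter-feature correlations of real texture tables), pure-noise columns
Normal(0, 1).  Default layout 34+18 samples, 8+6+14 columns, Δ = 2.

## Problem sizes in tests and reproduction script

The test suite and `scripts/acceptance.py` use reduced sizes chosen to
keep full runs in the minutes range: 192×192 images for the 20-dataset
variant study (the generator's class contrast does not depend on image
size), 128×128 for unit fixtures, 100 seeds × (60 × 28) matrices for the
support-recovery study, and 8 images for the distance-stability scan.
Solver cross-checks run at n = 40, p = 10 (50 seeds) against
coordinate-descent Lasso and at n = 25, p = 8 (100 seeds) for objective
monotonicity.

## Known limitations

* ISTA (no acceleration, by design) converges slowly on ill-conditioned
  problems at very small λ₁; such fits are flagged via `converged` and
  the step-norm criterion can trigger before high-precision optimality.
* The quantization does not adapt to per-image dynamic range; images
  using a narrow band of gray values occupy few levels.
* Shape ratios inherit discretization error of order 1–3% at radii
  ~10 px and below; components under the 20 px area floor are ignored.
* The accuracy-mode penalty rule is intentionally not the default (see
  above); EBIC assumes the residual scale is informative and will prefer
  dense fits when the regression residual becomes very small.
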