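# Methods

`usradiomics` re-implements an ultrasound-radiomics analysis for
predicting lateral cervical lymph-node metastasis (lateral LNM) in
conventional papillary thyroid carcinoma from B-mode images of the
primary tumor: ROI preprocessing → 730-feature texture panel →
LASSO-selected logistic signature (Rad-score) → ROC/AUC evaluation,
plus a synthetic speckle-cohort generator that makes every stage
testable without patient data.

## ROI preprocessing

Input images are 8-bit grayscale or RGB rasters with a binary tumor
mask. RGB collapses to luminance with the ITU-R BT.601 weights
(0.299 R + 0.587 G + 0.114 B, rounded half-to-even) — the standard
"drop hue and saturation, keep luminance" conversion. The ROI patch is
the mask's tight bounding box; pixels outside the mask never enter any
statistic (a metamorphic test corrupts them and asserts bit-identical
features).

Patches are z-normalized within the ROI (population SD). A constant
ROI normalizes to all zeros and raises a degeneracy flag instead of
erroring. For texture matrices, intensities are clipped to the
1st–99th percentile of the masked distribution and binned into G = 32
equal-width gray levels (bin 1 = clipped minimum, bin G = maximum).
G, the clipping percentiles, the GLCM distance and the wavelet are all
configurable; the defaults are declared package choices, since the
normalization formula and quantization depth are not uniquely fixed by
the source description of the analysis.

## The 730-feature panel

Per channel, the panel computes

* 14 first-order statistics (mean, variance, SD, skewness, kurtosis
  [Pearson, normal → 3], energy Σx², Shannon entropy and uniformity on
  a 32-bin histogram, min, max, median, range, RMS, mean absolute
  deviation);
* 22 GLCM statistics at distance 1 for each angle in
  {0°, 45°, 90°, 135°} (Haralick set plus normalized inverse-difference
  variants and the marginal mean), on the symmetric unit-sum
  co-occurrence matrix restricted to pixel pairs wholly inside the mask;
* 11 GLRLM run-emphasis statistics (SRE, LRE, GLN, RLN, RP, LGRE,
  HGRE, SRLGE, SRHGE, LRLGE, LRHGE) for the same four angles; runs
  break at mask boundaries.

Channels are the normalized ROI plus the four subbands (LL, LH, HL,
HH) of a single-level Haar DWT with symmetric padding. Before the
transform, pixels outside the mask are replaced by the masked mean
(zero after normalization) so that out-of-ROI values cannot leak into
subband coefficients; the perfect-reconstruction contract applies to
this mean-filled patch. The subband mask is the ROI mask downsampled
by a 2×2 block-any rule, and each subband is re-quantized independently
with the same G and clipping.

Totals: 5 channels × (14 + 22·4 + 11·4) = 730 named, ordered features.
The registry (`usradiomics.registry`) is data-driven — channels and
angles are parameters — with 730 as the default-configuration
invariant asserted at import. The per-angle (not angle-averaged)
convention is what makes the arithmetic close at 730; it is one
consistent reconstruction of that printed total. Degenerate statistics
(e.g. GLCM correlation of a constant patch) return 0 with a per-feature
flag, so constant ROIs survive the pipeline.

## Signature model

The signature is L1-penalized logistic regression of the binary
lateral-LNM label on standardized features:

minimize (1/n) Σᵢ log(1 + exp(−tᵢ(β₀ + xᵢᵀβ))) + λ‖β‖₁,  tᵢ = ±1,

intercept unpenalized. Before fitting, features that are constant or
non-finite across the training cohort are dropped (the analogue of the
730 → 727 pre-filter in the source analysis), and the survivors are
z-scored with training-cohort constants only — validation data never
touch μ or σ.

λ is tuned on a 100-point log-spaced grid from λ_max (the smallest
penalty at which the null model is optimal, max|Xᵀ(y − ȳ)|/n) down to
10⁻³ λ_max, by stratified 10-fold cross-validation. The default
selection metric is the cross-validated AUC (mean over folds, with its
standard error), matching a tuning curve plotted as AUC versus log λ;
binomial deviance is available by configuration. λ_min is the grid
point attaining the optimal mean CV metric, ties broken toward the
larger (sparser) λ. Folds are stratified with a fixed default seed.

The optimizer is an in-package glmnet-style path solver: outer IRLS
quadratic approximations, inner cyclic coordinate descent with
soft-thresholding, warm starts along the descending grid, and
active-set sweeps with full-sweep KKT checks (numba-compiled). At a
fixed λ its solution matches direct Nelder-Mead optimization of the
penalized likelihood to < 1e-4 (tested). The nonzero-coefficient count
is non-decreasing as λ descends up to occasional single-feature
drop-outs, which are genuine lasso-path behaviour; the tests allow
these rare dips rather than asserting strict monotonicity.

The fitted signature serializes as JSON: λ, intercept, the nonzero
standardized-scale coefficients, and the per-feature (μ, σ). The
Rad-score of a patient is β₀ + Σ βᵢ(xᵢ − μᵢ)/σᵢ; a missing feature is
an error, never silently imputed.

## Evaluation statistics

AUC is computed by the midrank Mann-Whitney identity
(U/(n₁n₀), tie-aware) and its 95% CI by the DeLong placement-value
variance estimator; the two AUC routes are asserted equal to 1e-12 on
every call, and a percentile bootstrap CI (2,000 stratified resamples)
is available by configuration. Empirical coverage of the DeLong
interval is verified by simulation (two unit-variance Gaussians,
true AUC 0.7, n = 100/100, 1,000 replicates; coverage within
[0.92, 0.98]).

Group comparisons follow the conventions of base R: Mann-Whitney U for
continuous variables (exact enumeration when n₁+n₂ ≤ 10 and no ties,
tie-corrected normal approximation otherwise) and the Pearson
chi-square for categorical ones. On 2×2 tables the Yates continuity
correction is applied by default — this is what reproduces the
published p = 0.045 for the lateral-LNM-by-cohort table of counts
[[83, 317], [100, 268]]; the uncorrected statistic (which gives 0.037
there) is available with `correction=False`.

## Synthetic cohorts

The generator emulates the first-order structure of B-mode speckle:
image = clip₀…₂₅₅(round(M · S)), where M is a smooth base intensity
field (Gaussian-blurred white noise, mean 120, amplitude 25,
correlation length 16 px) and S is unit-mean Gamma(k = 4)
multiplicative noise blurred with a Gaussian of width s. The class
signal enters through the speckle correlation length: LN-negative
tumors use s = 1 px, LN-positive s = 1 + δ with δ = 2 by default;
δ = 0 is the null configuration in which both classes share one image
law. Tumors are uniformly random ellipses (semi-axes 10–28 px,
arbitrary rotation) strictly inside a 128×128 image. Labels are i.i.d.
Bernoulli at the study prevalences (0.21 training, 0.27 validation);
covariates (age ~ N(45, 13) truncated to [17, 80], sex 85% female,
log-normal tumor size with median 17 mm, central-LNM status) are drawn
from cohort-like distributions but carry no signal by default — the
signature is image-only. An optional flag couples central-LNM status
to the label (90% vs 49% positivity) for table-reproduction demos.

What this generator does *not* model: point-spread/RF physics,
attenuation, shadowing, anisotropic speckle, operator variability, or
any relationship between texture and true tumor biology. Passing the
end-to-end tests therefore shows that the pipeline detects and
calibrates texture differences of the kind it targets — not that the
published clinical effect sizes are reproducible from images this
package can make. Correlation-length differences are a deliberately
strong signal for co-occurrence features: at δ = 2 the synthetic
classes separate almost perfectly, and the weak-signal regime
(δ ≈ 0.05) is the one that visually resembles the published
training/validation AUC pattern (≈0.92/0.76 vs the published
0.710/0.621).

## Problem sizes and numerical choices

The package's evaluation runs use these sizes, chosen to keep the full
suite fast while preserving the study design: end-to-end Monte-Carlo
studies run on 64×64 images with the study cohort sizes (n = 400
training / 368 validation) and the *evaluation grid* — 30 log-spaced
penalties down to 0.05 λ_max with fold fits at a loosened
coordinate-descent tolerance (1e-4, ≤10 IRLS steps); the acceptance
script uses the same grid on 128×128 images. The held-out AUC that
drives λ selection is insensitive to coefficient noise far below the
score ranking, and penalties beyond 0.05 λ_max only grow models past
a hundred correlated features, a regime a 14-feature signature never
occupies. The library defaults for real-data fits remain the full
100-point grid to 10⁻³ λ_max at tolerance 1e-7; the path solver also
terminates early, as glmnet does, when the training deviance saturates
(>99.9% of null deviance explained) or stops improving (<1e-5
relative), and cross-validation evaluates only the penalties every
fold reached. Exhaustive texture-matrix verification covers every
2-level patch of every shape up to 4×4 and every 3×3 patch over
{masked, level 1, level 2}.

Numerical details: coordinate-descent tolerance 1e-7 on coefficient
changes (1e-10 for fixed-λ reference fits), IRLS weights floored at
1e-5, probabilities clipped at 1e-8; quantization maps the clipped
minimum to bin 1 and maximum to bin G; GLCM entropies use log₂ with
0·log 0 = 0; DeLong CIs are truncated to [0, 1]. All randomness flows
from explicit `numpy.random.Generator` seeds; there is no global RNG
state anywhere in the package.

## Known limitations

* The exact statistic list, quantization and normalization of the
  original in-house MATLAB implementation are unpublished; the panel
  here is a declared, configurable reconstruction constrained by the
  printed feature total.
* The published AUCs were computed on 768 patients' real ultrasound
  images that are not publicly available; nothing here claims to
  reproduce those numbers, only the methodology and its qualitative
  behaviour (signal detection, null calibration, training-validation
  optimism).
* Only first-order, texture and wavelet features are implemented — no
  shape, margin or position features, mirroring the source analysis.
* The chi-square default (Yates on 2×2) and the CV metric (AUC at the
  minimum criterion) are the choices that best match the published
  numbers; both are configurable.
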